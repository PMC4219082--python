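"""Hounsfield-unit density distributions.

For one slice, ``lambda_p`` is the percentage of retained intracranial
pixels having HU value ``lambda`` (an integer in 0..79).  A series
distribution is the unweighted mean of the per-slice proportion vectors,

    (1/n) * sum_k lambda_p^k ,

i.e. every image contributes equally regardless of its interior size.  A
pooled-pixel alternative (weight slices by pixel count) is available behind
``pooled=True`` for sensitivity analysis.  ``HU_a^b`` -- the band
proportion -- is the inclusive sum of lambda_p over a to b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError, LevelError
from .image_io import CTSeries
from .segmentation import SegConfig, SegmentationResult, segment_slice

__all__ = [
    "N_BINS",
    "DensityDistribution",
    "BandQuery",
    "slice_distribution",
    "series_distribution",
    "group_distribution",
    "band_proportion",
    "subject_distribution",
]

N_BINS = 80  # integer HU 0..79, the boundary condition of the analysis

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DensityDistribution:
    """An 80-bin proportion vector (percent) at slice, series or group level."""

    proportions: np.ndarray
    level: str = "slice"  # {"slice", "series", "group"}
    n_images: int = 1
    n_pixels: int = 0

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {p.shape}")
        if np.any(p < -_SUM_TOL) or np.any(p > 100 + _SUM_TOL):
            raise ValueError("proportions must lie in [0, 100]")
        if abs(p.sum() - 100.0) > 1e-6:
            raise ValueError(f"proportions must sum to 100, got {p.sum()!r}")
        object.__setattr__(self, "proportions", p)

    def __getitem__(self, hu: int) -> float:
        return float(self.proportions[hu])


@dataclass(frozen=True)
class BandQuery:
    """Inclusive HU band [alpha, beta] within 0..79."""

    alpha: int
    beta: int

    def __post_init__(self):
        if not (0 <= self.alpha <= self.beta <= N_BINS - 1):
            raise ValueError(f"invalid band [{self.alpha}, {self.beta}]")


def slice_distribution(seg: SegmentationResult) -> DensityDistribution:
    """lambda_p of one segmented slice: 100 * count(HU = lambda) / count(all)."""
    retained = np.asarray(seg.retained_pixels)
    if retained.size == 0:
        raise EmptyRegionError("no retained pixels")
    counts = np.bincount(retained, minlength=N_BINS)[:N_BINS]
    props = 100.0 * counts / retained.size
    return DensityDistribution(proportions=props, level="slice",
                               n_images=1, n_pixels=int(retained.size))


def series_distribution(dists: list[DensityDistribution],
                        pooled: bool = False) -> DensityDistribution:
    """Average the per-slice proportion vectors of one examination.

    Default is the unweighted mean over slices; ``pooled=True`` weights each
    slice by its retained pixel count (equivalent to pooling all pixels).
    """
    if not dists:
        raise ValueError("need at least one slice distribution")
    if any(d.level != "slice" for d in dists):
        raise LevelError("series_distribution expects slice-level inputs")
    mat = np.stack([d.proportions for d in dists])
    if pooled:
        w = np.array([d.n_pixels for d in dists], dtype=np.float64)
        props = (mat * w[:, None]).sum(axis=0) / w.sum()
    else:
        props = mat.mean(axis=0)
    return DensityDistribution(
        proportions=props, level="series", n_images=len(dists),
        n_pixels=int(sum(d.n_pixels for d in dists)),
    )


def group_distribution(series_dists: list[DensityDistribution]
                       ) -> tuple[DensityDistribution, np.ndarray]:
    """Mean distribution across subjects plus the per-subject matrix.

    Returns ``(group_dist, matrix)`` where ``matrix`` is subjects x 80 and
    feeds the per-bin statistical scan.
    """
    if not series_dists:
        raise ValueError("need at least one series distribution")
    if any(d.level != "series" for d in series_dists):
        raise LevelError("group_distribution expects series-level inputs")
    mat = np.stack([d.proportions for d in series_dists])
    dist = DensityDistribution(
        proportions=mat.mean(axis=0), level="group",
        n_images=int(sum(d.n_images for d in series_dists)),
        n_pixels=int(sum(d.n_pixels for d in series_dists)),
    )
    return dist, mat


def band_proportion(dist: DensityDistribution, band: BandQuery) -> float:
    """HU_alpha^beta: percentage of pixels with alpha <= HU <= beta (inclusive)."""
    return float(dist.proportions[band.alpha:band.beta + 1].sum())


def subject_distribution(series: CTSeries, config: SegConfig = SegConfig(),
                         pooled: bool = False) -> DensityDistribution:
    """Segment every slice of a series and average the valid distributions.

    Slices with no retained pixels or with interiors smaller than
    ``config.min_interior_px`` do not count toward n.
    """
    dists = []
    for slc in series.slices:
        try:
            seg = segment_slice(slc, config)
        except EmptyRegionError:
            continue
        if int(seg.stages["interior"].sum()) < config.min_interior_px:
            continue
        dists.append(slice_distribution(seg))
    if not dists:
        raise EmptyRegionError("no usable slices in series")
    return series_distribution(dists, pooled=pooled)
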