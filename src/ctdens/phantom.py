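"""Synthetic head-CT phantoms with ground truth.

The generator renders 512x512-style axial slices containing every object
class the artifact-elimination pipeline must handle: an elliptical cranial
shell (~1000 HU), extracranial scalp whose HU overlaps brain tissue, air
background, a gantry/head-rest arc touching the image border, fracture gaps
and craniotomy arcs in the shell, an intraparenchymal catheter (metal,
3000 HU) and air bubbles (-1000 HU).  Interior tissue is drawn from a
discrete HU mixture on 0..79 (CSF around 8 HU, parenchyma around 24-29 HU,
blood around 55 HU), so the exact intracranial HU distribution is known.

Cohort simulation adds a subject level: each subject receives a perturbed
tissue mixture (mode/width/weight jitter plus per-bin roughness), and
"severe"-type subjects carry ``band_mass_shift`` additional percentage
points of mass in the HU 17-24 band, the dial the statistical machinery is
asked to recover.  Subject distributions can be sampled directly (fast
path used by the statistical experiments) or rendered into image series
and pushed through segmentation.

Reproducibility: all randomness flows from ``numpy.random.SeedSequence``;
slice k of subject j uses ``SeedSequence(master_seed).spawn()`` children in
a fixed (subject, slice) order, so any subset regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import N_BINS, DensityDistribution
from .image_io import CTSlice, CTSeries

__all__ = [
    "TissueComponent",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "make_phantom",
    "make_series",
    "random_recovery_spec",
    "subject_pmf",
    "sample_distribution",
    "simulate_cohort_distributions",
    "simulate_cohort",
]

AIR_HU = -1000
BONE_HU = 1000
METAL_HU = 3000

CES_LO, CES_HI = 17, 24  # discriminative band the cohort dial acts on


@dataclass(frozen=True)
class TissueComponent:
    """One mixture component of intracranial tissue HU."""

    mean: float
    sd: float
    weight: float


DEFAULT_TISSUE = (
    TissueComponent(8.0, 4.0, 0.12),    # CSF
    # parenchymal width 4.7 HU makes the reference mild mixture's HU 17-24
    # mass equal the observed mild-group median CES (~14.3 %)
    TissueComponent(29.0, 4.7, 0.85),   # parenchyma
    TissueComponent(55.0, 8.0, 0.03),   # blood
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue model and artifact flags for one phantom slice."""

    shape: tuple[int, int] = (512, 512)
    center: tuple[float, float] | None = None  # defaults to the grid centre
    semi_axes: tuple[float, float] = (150.0, 120.0)  # (row, col) semi-axes
    shell_thickness: float = 6.0
    scalp_thickness: float = 14.0
    tissue_model: tuple[TissueComponent, ...] = DEFAULT_TISSUE
    tissue_pmf: np.ndarray | None = None  # overrides tissue_model when given
    fractures: tuple[tuple[float, float], ...] = ()   # (angle_deg, width_px)
    craniotomy: tuple[tuple[float, float], ...] = ()  # (start_deg, span_deg)
    evd: bool = False
    air_bubble: bool = False
    gantry: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.shell_thickness < 2:
            raise ValueError("shell thickness must be >= 2 px")
        if self.tissue_pmf is None:
            w = sum(c.weight for c in self.tissue_model)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"component weights must sum to 1, got {w}")
        rows, cols = self.shape
        cr, cc = self.center if self.center is not None else (rows / 2, cols / 2)
        a, b = self.semi_axes
        margin = self.scalp_thickness + 2
        if (cr - a - margin < 0 or cr + a + margin >= rows
                or cc - b - margin < 0 or cc + b + margin >= cols):
            raise ValueError("phantom geometry does not fit inside the grid")

    @property
    def centre(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.shape[0] / 2, self.shape[1] / 2)


def random_recovery_spec(seed: int) -> PhantomSpec:
    """A randomized single-slice phantom for mask-recovery studies.

    Draws geometry jitter, zero to two fractures up to 20 px wide, a
    craniotomy arc up to 90 degrees half the time, and independent
    EVD / air-bubble / gantry artifacts, spanning the conditions the
    segmentation pipeline is expected to survive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x5EC0, seed]))
    centre = (256.0 + rng.uniform(-10, 10), 256.0 + rng.uniform(-10, 10))
    axes = (150.0 + rng.uniform(-12, 12), 120.0 + rng.uniform(-10, 10))
    fractures = tuple(
        (float(rng.uniform(0, 360)), float(rng.uniform(0, 20)))
        for _ in range(rng.integers(0, 3))
    )
    craniotomy = ()
    if rng.random() < 0.5:
        craniotomy = ((float(rng.uniform(0, 360)), float(rng.uniform(0, 90))),)
    return PhantomSpec(
        center=centre,
        semi_axes=axes,
        shell_thickness=float(rng.uniform(4, 8)),
        fractures=fractures,
        craniotomy=craniotomy,
        evd=bool(rng.random() < 0.5),
        air_bubble=bool(rng.random() < 0.5),
        gantry=bool(rng.random() < 0.5),
        seed=seed,
    )


@dataclass
class PhantomTruth:
    """Ground truth for one phantom slice."""

    intracranial_mask: np.ndarray
    class_masks: dict[str, np.ndarray]
    true_distribution: DensityDistribution


def component_pmf(mean: float, sd: float) -> np.ndarray:
    """Discretized truncated normal over integer HU 0..79."""
    edges = np.arange(-0.5, N_BINS + 0.5)
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    pmf = np.diff(cdf)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("component has no mass in [0, 79]")
    return pmf / total


def _mixture_pmf(components) -> np.ndarray:
    pmf = np.zeros(N_BINS)
    for c in components:
        pmf += c.weight * component_pmf(c.mean, c.sd)
    return pmf / pmf.sum()


def _ellipse_interior(shape, centre, axes) -> np.ndarray:
    rr, cc = np.indices(shape)
    a, b = axes
    return ((rr - centre[0]) / a) ** 2 + ((cc - centre[1]) / b) ** 2 < 1.0


def _angle_map(shape, centre) -> np.ndarray:
    rr, cc = np.indices(shape)
    return np.arctan2(rr - centre[0], cc - centre[1])  # radians in (-pi, pi]


def _angular_window(theta: np.ndarray, centre_deg: float, half_deg: float) -> np.ndarray:
    d = np.rad2deg(theta) - centre_deg
    d = (d + 180.0) % 360.0 - 180.0
    return np.abs(d) <= half_deg


def _ellipse_radius(axes, theta: float) -> float:
    a, b = axes
    return 1.0 / np.hypot(np.sin(theta) / a, np.cos(theta) / b)


def make_phantom(spec: PhantomSpec,
                 rng: np.random.Generator | None = None) -> tuple[CTSlice, PhantomTruth]:
    """Render one phantom slice and its ground truth.

    Deterministic for a fixed ``spec.seed``; the truth distribution is the
    exact histogram of in-bounds intracranial pixels as rendered.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, cols = spec.shape
    centre = spec.centre
    a, b = spec.semi_axes
    t = spec.shell_thickness

    outer = _ellipse_interior(spec.shape, centre, (a, b))
    inner = _ellipse_interior(spec.shape, centre, (a - t, b - t))
    scalp_zone = _ellipse_interior(
        spec.shape, centre, (a + spec.scalp_thickness, b + spec.scalp_thickness)
    ) & ~outer
    ring = outer & ~inner

    pixels = np.full(spec.shape, AIR_HU, dtype=np.int32)
    classes = {k: np.zeros(spec.shape, dtype=bool)
               for k in ("bone", "scalp", "csf", "tissue", "blood",
                         "artifact", "fracture")}

    # scalp: soft tissue + skin, partly overlapping brain HU, some fat below 0
    n_scalp = int(scalp_zone.sum())
    pixels[scalp_zone] = np.clip(
        np.rint(rng.normal(45.0, 15.0, n_scalp)), -120, 79
    ).astype(np.int32)
    classes["scalp"] = scalp_zone

    # cranial shell
    n_ring = int(ring.sum())
    pixels[ring] = np.clip(
        np.rint(rng.normal(BONE_HU, 60.0, n_ring)), 400, None
    ).astype(np.int32)
    classes["bone"] = ring.copy()

    # shell defects: fractures (narrow) and craniotomy arcs (wide)
    theta = _angle_map(spec.shape, centre)
    defect = np.zeros(spec.shape, dtype=bool)
    for angle_deg, width_px in spec.fractures:
        if width_px <= 0:
            continue
        r_shell = _ellipse_radius((a - t / 2, b - t / 2), np.deg2rad(angle_deg))
        half_deg = np.rad2deg(width_px / (2.0 * r_shell))
        defect |= ring & _angular_window(theta, angle_deg, half_deg)
    for start_deg, span_deg in spec.craniotomy:
        if span_deg <= 0:
            continue
        defect |= ring & _angular_window(theta, start_deg + span_deg / 2.0,
                                         span_deg / 2.0)
    if defect.any():
        pixels[defect] = np.clip(
            np.rint(rng.normal(32.0, 9.0, int(defect.sum()))), 0, 79
        ).astype(np.int32)
        classes["bone"] &= ~defect
        classes["fracture"] = defect

    # intracranial tissue
    interior = inner
    n_int = int(interior.sum())
    if spec.tissue_pmf is not None:
        pmf = np.asarray(spec.tissue_pmf, dtype=np.float64)
        hu = rng.choice(N_BINS, size=n_int, p=pmf / pmf.sum()).astype(np.int32)
        pixels[interior] = hu
        # approximate class split by HU range when only a pmf is given
        csf = interior.copy(); csf[interior] = hu <= 15
        blood = interior.copy(); blood[interior] = hu >= 45
        classes["csf"] = csf
        classes["blood"] = blood
        classes["tissue"] = interior & ~csf & ~blood
    else:
        comps = spec.tissue_model
        weights = np.array([c.weight for c in comps])
        which = rng.choice(len(comps), size=n_int, p=weights)
        hu = np.empty(n_int, dtype=np.int32)
        for i, c in enumerate(comps):
            sel = which == i
            if sel.any():
                hu[sel] = rng.choice(N_BINS, size=int(sel.sum()),
                                     p=component_pmf(c.mean, c.sd))
        pixels[interior] = hu
        names = ("csf", "tissue", "blood")
        for i, name in enumerate(names[: len(comps)]):
            m = interior.copy()
            m[interior] = which == i
            classes[name] = m

    # catheter: metal tract deep in the parenchyma, detached from the shell
    if spec.evd:
        ang = np.deg2rad(rng.uniform(0, 360))
        r_lo, r_hi = 0.08 * min(a, b), 0.5 * min(a, b)
        rs = np.arange(r_lo, r_hi, 0.4)
        for rr_off in (-0.6, 0.0, 0.6):
            rpix = np.rint(centre[0] + (rs + rr_off) * np.sin(ang)).astype(int)
            cpix = np.rint(centre[1] + rs * np.cos(ang) + rr_off).astype(int)
            pixels[rpix, cpix] = METAL_HU
            classes["artifact"][rpix, cpix] = True

    # intracranial air bubble
    if spec.air_bubble:
        ang = np.deg2rad(rng.uniform(0, 360))
        r = 0.35 * min(a, b)
        brow = centre[0] + r * np.sin(ang)
        bcol = centre[1] + r * np.cos(ang)
        bubble = _ellipse_interior(spec.shape, (brow, bcol), (4.0, 4.0)) & interior
        pixels[bubble] = AIR_HU
        classes["artifact"] |= bubble

    # gantry / head rest: two arc lobes below the head, touching the border
    if spec.gantry:
        gc = (centre[0] + 120.0, centre[1])
        rr, cc = np.indices(spec.shape)
        dist = np.hypot(rr - gc[0], cc - gc[1])
        phi = np.rad2deg(np.arctan2(cc - gc[1], rr - gc[0]))  # 0 = straight down
        band = (dist >= 248) & (dist <= 262) & (np.abs(phi) >= 50) & (np.abs(phi) <= 82)
        band &= pixels == AIR_HU
        pixels[band] = np.clip(
            np.rint(rng.normal(300.0, 50.0, int(band.sum()))), 160, None
        ).astype(np.int32)
        classes["artifact"] |= band

    # artifacts overwrite tissue pixels; keep the class masks disjoint
    for name in ("csf", "tissue", "blood"):
        classes[name] &= ~classes["artifact"]

    in_bounds = interior & (pixels >= 0) & (pixels <= 79)
    counts = np.bincount(pixels[in_bounds], minlength=N_BINS)[:N_BINS]
    true_dist = DensityDistribution(
        proportions=100.0 * counts / counts.sum(), level="slice",
        n_images=1, n_pixels=int(counts.sum()),
    )
    truth = PhantomTruth(
        intracranial_mask=interior,
        class_masks=classes,
        true_distribution=true_dist,
    )
    slc = CTSlice(pixels=pixels, slice_index=0,
                  source_id=f"phantom-seed{spec.seed}")
    return slc, truth


def make_series(spec: PhantomSpec, n_slices: int) -> tuple[CTSeries, list[PhantomTruth]]:
    """Render a vertex->caudal series by scaling the cranial geometry.

    Slice i uses semi-axes scaled by sqrt(1 - z_i^2) with z_i decreasing
    linearly from 0.85 (small vertex slice) to 0; per-slice RNGs are spawned
    from the master seed in slice order.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_slices)
    slices, truths = [], []
    for i in range(n_slices):
        z = 0.85 * (1 - i / (n_slices - 1)) if n_slices > 1 else 0.0
        s = float(np.sqrt(1.0 - z * z))
        sub = replace(spec, semi_axes=(spec.semi_axes[0] * s,
                                       spec.semi_axes[1] * s))
        slc, truth = make_phantom(sub, rng=np.random.default_rng(children[i]))
        slices.append(replace(slc, slice_index=i))
        truths.append(truth)
    return CTSeries(slices=tuple(slices), subject_id=f"phantom-{spec.seed}"), truths


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-condition dials for a simulated cohort.

    Group sizes default to the reference study cohort composition (37 mild, 33
    severe of whom 8 delayed; 6 deceased).  ``mild_tissue_mode`` /
    ``severe_tissue_mode`` place the parenchymal histogram peaks (29 vs 24
    HU); ``band_mass_shift`` is the extra band mass (percentage points of
    HU 17-24) carried by severe-type subjects, defaulting to the observed
    median CES gap of about 8 points.  ``ces_sd`` is the between-subject
    spread of band mass within a group.  Delayed and deceased subjects are
    generated with severe parameters and differ only in label.
    """

    n_mild: int = 37
    n_severe: int = 19
    n_delayed: int = 8
    n_deceased: int = 6
    mild_tissue_mode: float = 29.0
    severe_tissue_mode: float = 24.0
    band_mass_shift: float = 8.0
    ces_sd: float = 3.0
    mode_jitter_sd: float = 2.5
    width_jitter_sd: float = 1.2
    weight_jitter_sd: float = 0.015
    roughness_sd: float = 0.25
    slices_per_subject: int = 12
    pixels_per_slice: int = 30000
    grid: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self):
        for f in ("n_mild", "n_severe", "n_delayed", "n_deceased"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_mild + self.n_severe + self.n_delayed + self.n_deceased == 0:
            raise ValueError("cohort must contain at least one subject")
        for f in ("mild_tissue_mode", "severe_tissue_mode"):
            if not (0 <= getattr(self, f) <= 79):
                raise ValueError(f"{f} must lie within 0..79")

    @property
    def labels(self) -> list[str]:
        return (["mild"] * self.n_mild + ["severe"] * self.n_severe
                + ["delayed"] * self.n_delayed + ["deceased"] * self.n_deceased)


def _base_components(mode: float) -> tuple[TissueComponent, ...]:
    return (
        TissueComponent(8.0, 4.0, 0.12),
        TissueComponent(mode, 4.7, 0.85),
        TissueComponent(55.0, 8.0, 0.03),
    )


def _band_mass(pmf: np.ndarray) -> float:
    return float(pmf[CES_LO:CES_HI + 1].sum())


def _calibrate_band(pmf: np.ndarray, target_frac: float,
                    parenchyma_share: np.ndarray | None = None) -> np.ndarray:
    """Rescale a pmf so its HU 17-24 mass equals ``target_frac`` exactly.

    The compensating mass outside the band is exchanged with the
    parenchymal part of each bin (weighted by ``parenchyma_share``): edema
    converts normal parenchyma into band-density tissue, while CSF and
    blood pools are untouched.  Without a share vector the exchange is
    proportional to the whole out-of-band mass.
    """
    cur = _band_mass(pmf)
    out = pmf.copy()
    out[CES_LO:CES_HI + 1] *= target_frac / cur
    mask = np.ones(N_BINS, dtype=bool)
    mask[CES_LO:CES_HI + 1] = False
    delta = target_frac - cur  # mass to remove from outside the band
    if parenchyma_share is None:
        weights = pmf[mask]
    else:
        weights = pmf[mask] * parenchyma_share[mask]
    out[mask] -= delta * weights / weights.sum()
    if np.any(out < 0):  # extreme jitter; fall back to proportional scaling
        out[mask] = pmf[mask] * (1.0 - target_frac) / (1.0 - cur)
    return out / out.sum()


def subject_pmf(rng: np.random.Generator, cspec: CohortSpec, group: str,
                base_ces: float | None = None) -> np.ndarray:
    """Sample one subject's underlying HU pmf.

    Structure: jitter the mixture (parenchymal mode and width, component
    weights), roughen each bin with independent lognormal noise, then pin
    the HU 17-24 mass to the subject's band level ``b`` drawn around the
    group mean (mild: base CES; severe-type: base CES + band_mass_shift).
    """
    mode = cspec.mild_tissue_mode if group == "mild" else cspec.severe_tissue_mode
    comps = _base_components(mode)
    means = np.array([c.mean for c in comps])
    sds = np.array([c.sd for c in comps])
    weights = np.array([c.weight for c in comps])
    means[1] += rng.normal(0.0, cspec.mode_jitter_sd)
    sds[1] = max(3.0, sds[1] + rng.normal(0.0, cspec.width_jitter_sd))
    weights = np.clip(weights + rng.normal(0.0, cspec.weight_jitter_sd, 3), 0.005, None)
    weights /= weights.sum()
    parts = [w * component_pmf(float(np.clip(m, 1, 78)), float(s))
             for m, s, w in zip(means, sds, weights)]
    pmf = np.sum(parts, axis=0)
    with np.errstate(invalid="ignore"):
        par_share = np.where(pmf > 0, parts[1] / np.maximum(pmf, 1e-300), 0.0)
    pmf = pmf * np.exp(rng.normal(0.0, cspec.roughness_sd, N_BINS))
    pmf /= pmf.sum()
    if base_ces is None:
        base_ces = cohort_base_ces(cspec)
    target = base_ces + (0.0 if group == "mild" else cspec.band_mass_shift)
    target += rng.normal(0.0, cspec.ces_sd)
    target = float(np.clip(target, 1.0, 70.0))
    return _calibrate_band(pmf, target / 100.0, parenchyma_share=par_share)


def cohort_base_ces(cspec: CohortSpec) -> float:
    """Band mass (percent) of the unjittered mild mixture; the mild group mean."""
    return 100.0 * _band_mass(_mixture_pmf(_base_components(cspec.mild_tissue_mode)))


def sample_distribution(rng: np.random.Generator, pmf: np.ndarray,
                        n_pixels: int) -> tuple[DensityDistribution, float]:
    """Multinomial draw of ``n_pixels`` HU values from a subject pmf.

    Returns the observed series-level distribution and the true CES of the
    drawn pixels.
    """
    counts = rng.multinomial(n_pixels, pmf / pmf.sum())
    props = 100.0 * counts / n_pixels
    dist = DensityDistribution(proportions=props, level="series",
                               n_images=1, n_pixels=n_pixels)
    return dist, float(props[CES_LO:CES_HI + 1].sum())


def simulate_cohort_distributions(cspec: CohortSpec
                                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Fast path: subject distributions without image rendering.

    Returns ``(matrix, manifest)`` where ``matrix`` is subjects x 80 observed
    proportions and ``manifest`` records subject_id, label and true_ces.
    Identical CohortSpec (including seed) gives bit-identical output.
    """
    labels = cspec.labels
    ss = np.random.SeedSequence(cspec.seed)
    children = ss.spawn(len(labels))
    base = cohort_base_ces(cspec)
    n_pix = cspec.slices_per_subject * cspec.pixels_per_slice
    rows, mat = [], []
    for j, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        pmf = subject_pmf(rng, cspec, label, base_ces=base)
        dist, true_ces = sample_distribution(rng, pmf, n_pix)
        mat.append(dist.proportions)
        rows.append({"subject_id": f"S{j:03d}", "label": label,
                     "true_ces": true_ces})
    return np.array(mat), pd.DataFrame(rows)


@dataclass
class CohortSubject:
    subject_id: str
    label: str
    series: CTSeries
    truths: list[PhantomTruth]
    true_ces: float


def simulate_cohort(cspec: CohortSpec) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Render a full image-level cohort with ground truth.

    Each subject gets a phantom series whose interior tissue is drawn from
    the subject's pmf; the manifest records the label and the true CES of
    the rendered in-bounds intracranial pixels (series average).
    """
    labels = cspec.labels
    ss = np.random.SeedSequence(cspec.seed)
    children = ss.spawn(len(labels))
    base = cohort_base_ces(cspec)
    subjects, rows = [], []
    rows_px, cols_px = cspec.grid
    for j, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        pmf = subject_pmf(rng, cspec, label, base_ces=base)
        sid = f"S{j:03d}"
        pspec = PhantomSpec(
            shape=cspec.grid,
            semi_axes=(0.29 * rows_px, 0.23 * cols_px),
            scalp_thickness=max(4.0, 0.027 * rows_px),
            tissue_pmf=pmf,
            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
        )
        series, truths = make_series(pspec, cspec.slices_per_subject)
        series = CTSeries(slices=series.slices, subject_id=sid)
        per_slice = np.stack([t.true_distribution.proportions for t in truths])
        true_ces = float(per_slice.mean(axis=0)[CES_LO:CES_HI + 1].sum())
        subjects.append(CohortSubject(sid, label, series, truths, true_ces))
        rows.append({"subject_id": sid, "label": label, "true_ces": true_ces})
    return subjects, pd.DataFrame(rows)
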