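"""Six-stage artifact elimination for axial brain CT slices.

The pipeline isolates the intracranial pixels of one slice:

A. read the image (``image_io``)
B. locate the cranial shell and set up a quadrant frame on its interior
C. remove scanner hardware (gantry ring, head rest) touching the image border
D. seal shell discontinuities: narrow fracture gaps are bridged by
   interpolating the shell radius across the gap; craniotomy-scale defects
   are closed using the approximate left-right mirror symmetry of the
   cranium (pseudo-axisymmetric sealing)
E. flood-fill the sealed shell's interior, which excludes scalp and other
   convex tissue even where its HU overlaps brain tissue
F. keep only interior pixels inside the HU boundary condition [0, 79]

Pseudo-cranial pixels generated while sealing are temporary scaffolding:
they never appear among retained pixels or in any HU statistic.

Geometry is ray-based: ``ray_count`` rays are cast from the interior
centroid; a shell gap is a maximal circular run of rays that meet no bone.
All coordinates are relative to the centroid, which makes every stage
exactly equivariant under integer translations of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image, disk

from .errors import (
    EmptyRegionError,
    NoCraniumError,
    OpenShellError,
    SegmentationError,
    UnsealableCraniumError,
)
from .image_io import CTSlice

__all__ = [
    "SegConfig",
    "QuadrantFrame",
    "CranialShell",
    "SegmentationResult",
    "detect_cranium",
    "remove_gantry",
    "assign_quadrants",
    "seal_fractures",
    "seal_large_defects",
    "extract_intracranial",
    "apply_hu_bounds",
    "segment_slice",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegConfig:
    """Tunable parameters of the artifact-elimination pipeline.

    bone_threshold
        HU at or above which a pixel is a bone/foreign-body candidate.
        Cranial bone sits far above the 0-79 analysis window; 150 HU keeps
        partial-volume shell pixels while excluding soft tissue.
    ray_count
        Number of rays cast from the centroid for gap detection (720 =
        0.5 degree resolution).
    max_gap_deg
        Angular width up to which a shell gap counts as a fracture and is
        bridged by interpolation; wider gaps go to mirror sealing.
    close_radius_px
        Radius of the morphological closing used to group fracture-split
        shell arcs into one cranial component during detection.
    min_interior_px
        Slices whose interior is smaller than this are excluded from series
        distributions (vertex slices; proportion estimates unstable).
    """

    bone_threshold: int = 150
    ray_count: int = 720
    max_gap_deg: float = 15.0
    close_radius_px: int = 12
    min_interior_px: int = 100
    hu_lo: int = 0
    hu_hi: int = 79
    gantry_floor_hu: int = -500
    background_hu: int = -1024

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class QuadrantFrame:
    """Centroid of the cranial interior plus the two image-aligned axes
    through it, partitioning the grid into quadrants I-IV.

    Quadrants follow the usual anatomical-diagram convention on screen:
    I upper-right, II upper-left, III lower-left, IV lower-right, with the
    axis rows/columns assigned deterministically (boundary pixels go to the
    lower/right side).
    """

    centroid: tuple[float, float]
    shape: tuple[int, int]

    def quadrant_of(self, pixel: tuple[int, int]) -> str:
        r, c = pixel
        cr, cc = self.centroid
        upper = r < cr
        left = c < cc
        if upper and not left:
            return "I"
        if upper and left:
            return "II"
        if not upper and left:
            return "III"
        return "IV"

    def quadrant_map(self) -> np.ndarray:
        """Array of quadrant labels 1..4 for every pixel of the grid."""
        rr, cc = np.indices(self.shape)
        upper = rr < self.centroid[0]
        left = cc < self.centroid[1]
        out = np.full(self.shape, 4, dtype=np.uint8)
        out[upper & ~left] = 1
        out[upper & left] = 2
        out[~upper & left] = 3
        return out


@dataclass(frozen=True)
class CranialShell:
    """Cranial bone pixels plus the pseudo-cranial pixels added while sealing."""

    bone_mask: np.ndarray
    pseudo_mask: np.ndarray

    def __post_init__(self):
        if (self.bone_mask & self.pseudo_mask).any():
            raise ValueError("bone and pseudo-cranial masks must be disjoint")

    @property
    def sealed_mask(self) -> np.ndarray:
        return self.bone_mask | self.pseudo_mask


@dataclass
class SegmentationResult:
    """Intracranial mask and retained HU multiset for one slice.

    ``stages`` holds per-stage diagnostic masks: ``bone``, ``gantry_removed``,
    ``sealed`` (bone + pseudo), ``interior`` (stage E, before HU bounds) and
    ``final`` (= ``intracranial_mask``).
    """

    intracranial_mask: np.ndarray
    retained_pixels: np.ndarray
    stages: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage B: cranial shell detection
# ---------------------------------------------------------------------------

def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(np.unique(edge[edge > 0]).tolist())


def detect_cranium(slc: CTSlice, bone_threshold: int = 150,
                   close_radius_px: int = 12) -> np.ndarray:
    """Binary mask of the cranial shell.

    Bone candidates (HU >= ``bone_threshold``) are labeled 8-connected;
    components touching the grid border (scanner hardware) are discarded.
    The remaining candidates are morphologically closed so that arcs split
    by fractures rejoin, and the closed component that encloses the largest
    interior area is taken as the cranium (falling back to the largest
    component when no candidate encloses any area, as after a wide
    craniotomy).  Interior metal (EVD tips, ICP bolts) is rejected because
    it encloses nothing and is small.  An empty mask is a valid result and
    signals "no cranium" downstream.
    """
    cand = slc.pixels >= bone_threshold
    if not cand.any():
        return np.zeros_like(cand)
    labels, n = ndimage.label(cand, structure=_EIGHT)
    border = _border_labels(labels)
    keep = np.isin(labels, [i for i in range(1, n + 1) if i not in border])
    keep &= cand
    if not keep.any():
        return np.zeros_like(cand)
    # group arcs lying within 2*close_radius_px of each other (fracture
    # splits) by labeling the dilated mask; the dilated group also closes
    # such gaps, so its filled holes measure the enclosed interior
    grouped = ndimage.binary_dilation(keep, structure=disk(close_radius_px))
    glabels, gn = ndimage.label(grouped, structure=_EIGHT)
    best, best_key = 0, (-1, -1)
    for i in range(1, gn + 1):
        comp = glabels == i
        size = int((keep & comp).sum())
        hole = int(ndimage.binary_fill_holes(comp).sum()) - int(comp.sum())
        key = (hole, size)
        if key > best_key:
            best, best_key = i, key
    mask = keep & (glabels == best)
    if gn > 1:
        # craniotomy-scale defects can split the shell into arcs too far
        # apart to group by dilation; recover fellow arcs lying in the same
        # annulus around the winner (interior metal and hardware do not)
        hull = convex_hull_image(keep)
        cr, cc = ndimage.center_of_mass(hull)
        rr, ccx = np.nonzero(mask)
        r_med = float(np.median(np.hypot(rr - cr, ccx - cc)))
        win_size = int(mask.sum())
        for i in range(1, gn + 1):
            if i == best:
                continue
            comp = keep & (glabels == i)
            n = int(comp.sum())
            if n < max(20, 0.05 * win_size):
                continue
            rr, ccx = np.nonzero(comp)
            r_i = float(np.median(np.hypot(rr - cr, ccx - cc)))
            if 0.7 * r_med <= r_i <= 1.3 * r_med:
                mask = mask | comp
    return mask


# ---------------------------------------------------------------------------
# stage C: scanner hardware removal
# ---------------------------------------------------------------------------

def remove_gantry(slc: CTSlice, bone_mask: np.ndarray,
                  config: SegConfig = SegConfig()) -> CTSlice:
    """Erase connected components of the scanner itself.

    Any 8-connected component of pixels above ``gantry_floor_hu`` that
    touches the grid border and is disjoint from the cranial component is
    replaced with background HU.  Gantry rings and head rests always reach
    the border of an axial field of view; the head does not.
    """
    soft = slc.pixels > config.gantry_floor_hu
    labels, n = ndimage.label(soft, structure=_EIGHT)
    if n == 0:
        return slc
    head = set(np.unique(labels[bone_mask & soft]).tolist()) - {0}
    doomed = _border_labels(labels) - head
    if not doomed:
        return slc
    out = slc.pixels.copy()
    out[np.isin(labels, sorted(doomed))] = config.background_hu
    return replace(slc, pixels=out)


# ---------------------------------------------------------------------------
# stage B': quadrant frame
# ---------------------------------------------------------------------------

def assign_quadrants(slc: CTSlice, bone_mask: np.ndarray) -> QuadrantFrame:
    """Quadrant frame centred on the cranial interior.

    The centroid is taken from the convex hull of the shell, which stays
    inside the interior even when a craniotomy removes part of the arc.
    """
    if not bone_mask.any():
        raise NoCraniumError("empty bone mask", stage="assign_quadrants")
    hull = convex_hull_image(bone_mask)
    cr, cc = ndimage.center_of_mass(hull)
    # quantize to 1/8 px so integer translations of the mask shift the
    # centroid (and hence every ray sample) bit-exactly
    cr, cc = round(8 * float(cr)) / 8, round(8 * float(cc)) / 8
    return QuadrantFrame(centroid=(cr, cc), shape=bone_mask.shape)


# ---------------------------------------------------------------------------
# ray casting shared by the sealing stages
# ---------------------------------------------------------------------------

@dataclass
class _RayProfile:
    angles: np.ndarray      # (K,) radians
    hit: np.ndarray         # (K,) bool
    r_first: np.ndarray     # (K,) float, nan when no hit
    r_last: np.ndarray


def _cast_rays(mask: np.ndarray, centroid: tuple[float, float],
               ray_count: int) -> _RayProfile:
    rows, cols = mask.shape
    cr, cc = centroid
    r_max = float(np.hypot(max(cr, rows - cr), max(cc, cols - cc))) + 1.0
    radii = np.arange(0.5, r_max, 0.5)
    angles = 2.0 * np.pi * np.arange(ray_count) / ray_count
    dy = np.sin(angles)[:, None] * radii[None, :]
    dx = np.cos(angles)[:, None] * radii[None, :]
    rr = np.rint(cr + dy).astype(np.int64)
    ccx = np.rint(cc + dx).astype(np.int64)
    valid = (rr >= 0) & (rr < rows) & (ccx >= 0) & (ccx < cols)
    hits = np.zeros(rr.shape, dtype=bool)
    hits[valid] = mask[rr[valid], ccx[valid]]
    hit_any = hits.any(axis=1)
    first_idx = np.argmax(hits, axis=1)
    last_idx = hits.shape[1] - 1 - np.argmax(hits[:, ::-1], axis=1)
    r_first = np.where(hit_any, radii[first_idx], np.nan)
    r_last = np.where(hit_any, radii[last_idx], np.nan)
    return _RayProfile(angles=angles, hit=hit_any, r_first=r_first, r_last=r_last)


def _missing_runs(hit: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of rays with no bone hit, as (start, length)."""
    k = hit.size
    if hit.all():
        return []
    if not hit.any():
        return [(0, k)]
    start = int(np.argmax(hit))  # rotate so position 0 is a hit
    rolled = np.roll(~hit, -start)
    runs, i = [], 0
    while i < k:
        if rolled[i]:
            j = i
            while j < k and rolled[j]:
                j += 1
            runs.append(((i + start) % k, j - i))
            i = j
        else:
            i += 1
    return runs


def _paint_ray_segment(pseudo: np.ndarray, centroid: tuple[float, float],
                       theta: float, r_in: float, r_out: float) -> None:
    cr, cc = centroid
    r_out = max(r_out, r_in + 1.5)  # enforce bridgeable thickness
    radii = np.arange(r_in, r_out + 0.25, 0.5)
    rr = np.rint(cr + np.sin(theta) * radii).astype(np.int64)
    ccx = np.rint(cc + np.cos(theta) * radii).astype(np.int64)
    ok = (rr >= 0) & (rr < pseudo.shape[0]) & (ccx >= 0) & (ccx < pseudo.shape[1])
    pseudo[rr[ok], ccx[ok]] = True


def _paint_run(pseudo: np.ndarray, centroid: tuple[float, float],
               angles: np.ndarray, r_in: np.ndarray, r_out: np.ndarray) -> None:
    """Paint a contiguous fan of radial segments with enforced radial overlap.

    Adjacent rays may disagree about the shell radius (mixed mirror axes,
    noisy flanks); widening each segment to its 3-ray neighbourhood
    min/max guarantees the painted band is radially connected.
    """
    k = len(angles)
    lo = np.array([r_in[max(0, j - 1):j + 2].min() for j in range(k)])
    hi = np.array([r_out[max(0, j - 1):j + 2].max() for j in range(k)])
    for j in range(k):
        _paint_ray_segment(pseudo, centroid, angles[j], lo[j], hi[j])


def _finalize_pseudo(pseudo: np.ndarray, bone: np.ndarray) -> np.ndarray:
    # one 8-connected dilation closes sub-pixel chinks between painted rays
    if pseudo.any():
        pseudo = ndimage.binary_dilation(pseudo, structure=_EIGHT)
    return pseudo & ~bone


# ---------------------------------------------------------------------------
# stage D: sealing
# ---------------------------------------------------------------------------

def seal_fractures(bone_mask: np.ndarray, frame: QuadrantFrame,
                   max_gap_deg: float = 15.0, ray_count: int = 720) -> CranialShell:
    """Bridge narrow shell gaps with pseudo-cranial pixels.

    Gaps no wider than ``max_gap_deg`` are filled along rays whose shell
    radius is interpolated linearly between the two intact flanks; wider
    gaps are left for :func:`seal_large_defects`.
    """
    if not bone_mask.any():
        raise NoCraniumError("empty bone mask", stage="seal_fractures")
    prof = _cast_rays(bone_mask, frame.centroid, ray_count)
    pseudo = np.zeros_like(bone_mask)
    k = ray_count
    deg_per_ray = 360.0 / k
    for start, length in _missing_runs(prof.hit):
        if length * deg_per_ray > max_gap_deg:
            continue
        left = (start - 1) % k
        right = (start + length) % k
        t = (np.arange(length) + 1) / (length + 1)
        idxs = [(start + j) % k for j in range(length)]
        # include the flanks so the bridge fuses with the intact shell
        angles = prof.angles[[left] + idxs + [right]]
        r_in = np.concatenate([[prof.r_first[left]],
                               (1 - t) * prof.r_first[left] + t * prof.r_first[right],
                               [prof.r_first[right]]])
        r_out = np.concatenate([[prof.r_last[left]],
                                (1 - t) * prof.r_last[left] + t * prof.r_last[right],
                                [prof.r_last[right]]])
        _paint_run(pseudo, frame.centroid, angles, r_in, r_out)
    return CranialShell(bone_mask=bone_mask,
                        pseudo_mask=_finalize_pseudo(pseudo, bone_mask))


def _mirror_index(k_idx: int, ray_count: int, axis: str) -> int:
    # vertical axis (anatomical midline): theta -> pi - theta
    # horizontal axis: theta -> -theta
    if axis == "vertical":
        return (ray_count // 2 - k_idx) % ray_count
    return (-k_idx) % ray_count


def seal_large_defects(shell: CranialShell, frame: QuadrantFrame,
                       ray_count: int = 720) -> CranialShell:
    """Close craniotomy-scale defects using cranial pseudo-axisymmetry.

    For each ray that meets no cranial (or pseudo-cranial) pixel, a
    pseudo-cranial segment is generated at the radius found on the ray
    mirrored across the vertical axis of the quadrant frame, falling back
    to the horizontal axis when the vertical mirror is also open.  If both
    mirrors are open the cranium is unsealable.
    """
    sealed = shell.sealed_mask
    if not sealed.any():
        raise NoCraniumError("empty shell", stage="seal_large_defects")
    prof = _cast_rays(sealed, frame.centroid, ray_count)
    if prof.hit.all():
        out = _repair_pinholes(shell, frame)
        if _interior_region(out.sealed_mask, frame.centroid) is None:
            raise UnsealableCraniumError(
                "ray-closed shell leaks and resists pinhole repair",
                stage="seal_large_defects",
            )
        return out
    pseudo_new = np.zeros_like(sealed)
    unsealable = []
    for start, length in _missing_runs(prof.hit):
        r_in = np.full(length, np.nan)
        r_out = np.full(length, np.nan)
        for j in range(length):
            idx = (start + j) % ray_count
            for axis in ("vertical", "horizontal"):
                m = _mirror_index(idx, ray_count, axis)
                if prof.hit[m]:
                    r_in[j] = prof.r_first[m]
                    r_out[j] = prof.r_last[m]
                    break
            else:
                unsealable.append(idx)
        if np.isnan(r_in).any():
            continue
        # anchor the mirrored radii to the measured shell at the run's
        # flanks; this absorbs the centroid offset a one-sided defect
        # induces and guarantees the bridge meets the cut ends
        left = (start - 1) % ray_count
        right = (start + length) % ray_count
        d_l = prof.r_first[left] - r_in[0]
        d_r = prof.r_first[right] - r_in[-1]
        tt = (np.arange(length) + 1) / (length + 1)
        corr = (1 - tt) * d_l + tt * d_r
        r_in += corr
        r_out += corr
        idxs = [(start + j) % ray_count for j in range(length)]
        angles = prof.angles[[left] + idxs + [right]]
        r_in = np.concatenate([[prof.r_first[left]], r_in, [prof.r_first[right]]])
        r_out = np.concatenate([[prof.r_last[left]], r_out, [prof.r_last[right]]])
        _paint_run(pseudo_new, frame.centroid, angles, r_in, r_out)
    if unsealable:
        raise UnsealableCraniumError(
            f"{len(unsealable)} rays open on both mirror axes",
            stage="seal_large_defects",
        )
    pseudo = _finalize_pseudo(shell.pseudo_mask | pseudo_new, shell.bone_mask)
    out = CranialShell(bone_mask=shell.bone_mask, pseudo_mask=pseudo)
    out = _repair_pinholes(out, frame)
    if _interior_region(out.sealed_mask, frame.centroid) is None:
        raise UnsealableCraniumError(
            "interior still open after mirror sealing", stage="seal_large_defects"
        )
    return out


def _repair_pinholes(shell: CranialShell, frame: QuadrantFrame) -> CranialShell:
    """Close sub-ray-resolution leaks (a few pixels) with a small morphological
    closing of the sealed shell; a no-op when the interior is already tight."""
    if _interior_region(shell.sealed_mask, frame.centroid) is not None:
        return shell
    patched = ndimage.binary_closing(shell.sealed_mask, structure=disk(3))
    pseudo = (shell.pseudo_mask | patched) & ~shell.bone_mask
    return CranialShell(bone_mask=shell.bone_mask, pseudo_mask=pseudo)


# ---------------------------------------------------------------------------
# stage E: interior extraction
# ---------------------------------------------------------------------------

def _interior_region(sealed: np.ndarray, centroid: tuple[float, float]) -> np.ndarray | None:
    """4-connected flood region of the centroid in the complement of the shell;
    None when that region leaks to the grid border (open shell)."""
    free = ~sealed
    labels, _ = ndimage.label(free, structure=_FOUR)
    r0, c0 = int(round(centroid[0])), int(round(centroid[1]))
    r0 = min(max(r0, 0), sealed.shape[0] - 1)
    c0 = min(max(c0, 0), sealed.shape[1] - 1)
    if sealed[r0, c0]:  # centroid landed on the shell; probe its neighbourhood
        nb = free[max(r0 - 2, 0):r0 + 3, max(c0 - 2, 0):c0 + 3]
        if not nb.any():
            return None
        dr, dc = np.argwhere(nb)[0]
        r0, c0 = max(r0 - 2, 0) + dr, max(c0 - 2, 0) + dc
    lab = labels[r0, c0]
    region = labels == lab
    if lab == 0 or lab in _border_labels(labels):
        return None
    return region


def extract_intracranial(slc: CTSlice, shell: CranialShell,
                         frame: QuadrantFrame | None = None) -> np.ndarray:
    """Connected interior of the sealed shell (stage E).

    Scalp and any other convex tissue outside the shell are excluded even
    when their HU overlaps brain tissue, because only the flood region of
    the centroid is kept.
    """
    if frame is None:
        frame = assign_quadrants(slc, shell.sealed_mask)
    region = _interior_region(shell.sealed_mask, frame.centroid)
    if region is None:
        raise OpenShellError("shell is not closed; seal it first",
                             stage="extract_intracranial")
    return region


# ---------------------------------------------------------------------------
# stage F: HU boundary condition
# ---------------------------------------------------------------------------

def apply_hu_bounds(slc: CTSlice, mask: np.ndarray, lo: int = 0,
                    hi: int = 79) -> SegmentationResult:
    """Drop mask pixels outside [lo, hi] HU (air cells, calcifications, metal)."""
    if mask.shape != slc.pixels.shape:
        raise ValueError("mask shape does not match slice")
    in_bounds = mask & (slc.pixels >= lo) & (slc.pixels <= hi)
    retained = slc.pixels[in_bounds]
    if retained.size == 0:
        raise EmptyRegionError("zero retained pixels", stage="apply_hu_bounds")
    return SegmentationResult(
        intracranial_mask=in_bounds,
        retained_pixels=np.sort(retained),
        stages={"interior": mask, "final": in_bounds},
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _fallback_region(slc: CTSlice, config: SegConfig) -> np.ndarray:
    """Region used when no cranial bone exists: the union of in-bounds
    components that do not touch the border.

    An already-segmented slice (background filled, shell removed) re-enters
    the pipeline through this path and reproduces its retained multiset
    exactly, making ``segment_slice`` idempotent.
    """
    in_bounds = (slc.pixels >= config.hu_lo) & (slc.pixels <= config.hu_hi)
    labels, n = ndimage.label(in_bounds, structure=_EIGHT)
    doomed = _border_labels(labels)
    keep = np.isin(labels, [i for i in range(1, n + 1) if i not in doomed])
    return keep & in_bounds


def segment_slice(slc: CTSlice, config: SegConfig = SegConfig()) -> SegmentationResult:
    """Run the full artifact-elimination pipeline on one slice.

    Equivalent to composing the individual stages; per-stage masks are
    recorded under ``result.stages``.  Stage errors propagate labeled with
    the stage that raised them.
    """
    bone = detect_cranium(slc, config.bone_threshold, config.close_radius_px)
    if not bone.any():
        region = _fallback_region(slc, config)
        if not region.any():
            raise EmptyRegionError("no cranium and no interior candidate region",
                                   stage="detect_cranium")
        res = apply_hu_bounds(slc, region, config.hu_lo, config.hu_hi)
        res.stages = {
            "bone": bone,
            "gantry_removed": np.zeros_like(bone),
            "sealed": np.zeros_like(bone),
            "interior": region,
            "final": res.intracranial_mask,
        }
        return res

    cleaned = remove_gantry(slc, bone, config)
    frame = assign_quadrants(cleaned, bone)
    shell = seal_fractures(bone, frame, config.max_gap_deg, config.ray_count)
    shell = seal_large_defects(shell, frame, config.ray_count)
    interior = extract_intracranial(cleaned, shell, frame)
    res = apply_hu_bounds(cleaned, interior, config.hu_lo, config.hu_hi)
    res.stages = {
        "bone": bone,
        "gantry_removed": slc.pixels != cleaned.pixels,
        "sealed": shell.sealed_mask,
        "interior": interior,
        "final": res.intracranial_mask,
    }
    return res
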