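# Methods

This note documents the models, algorithms and numerical choices behind
`ctdens`: what each stage assumes, which parameters matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## Densitometry model

Every retained intracranial pixel carries an integer HU value in 0–79.
λ_p is the per-image percentage of pixels at value λ; a series is
summarized by the unweighted mean of its per-image λ_p vectors, so each
image contributes equally regardless of interior size.  A pooled
alternative (weight images by retained pixel count) is available via
`series_distribution(..., pooled=True)` for sensitivity analysis; the two
differ only when interior sizes vary strongly across a series.  Band
proportions HU_α^β sum λ_p inclusively from α to β.  Distribution
invariants (sum = 100 within 1e-9, band nesting and additivity) are
enforced by construction and property-tested.

HU values are integers end to end.  DICOM rescale results are rounded
half-away-from-zero; the rounding mode is a package choice (binning is by
integer HU and no convention is canonical).  Fractional-HU binning is out
of scope.

## Artifact elimination

Assumptions: a single head per image; cranial bone far above the 0–79
analysis window; scanner hardware connected to the image border; the
cranium approximately mirror-symmetric about the anatomical midline.

Parameters (all in `SegConfig`):

| parameter | default | meaning |
|---|---|---|
| `bone_threshold` | 150 HU | bone/foreign-body candidate threshold; far above soft tissue (≤ ~100 HU), low enough to keep partial-volume shell pixels |
| `ray_count` | 720 | rays cast from the interior centroid (0.5° resolution) |
| `max_gap_deg` | 15° | widest angular gap treated as a fracture (radius-interpolated bridge); wider gaps use mirror sealing |
| `close_radius_px` | 12 px | grouping radius for fracture-split shell arcs (bridges splits up to ~24 px) |
| `min_interior_px` | 100 px | slices with smaller interiors (vertex slices) are excluded from series averages — proportion estimates there are unstable |
| `hu_lo`, `hu_hi` | 0, 79 | HU boundary condition |
| `gantry_floor_hu` | −500 HU | anything denser than this counts as an object when hunting border-connected hardware |

Algorithmic choices worth knowing:

* **Shell detection.** Bone candidates are labeled 8-connected;
  border-touching components are discarded as hardware.  Remaining arcs
  are grouped by labeling the dilated mask (a morphological closing cannot
  bridge a radially open fracture gap — the structuring element passes
  straight through it).  The group enclosing the largest filled-hole area
  wins; with no enclosing group (wide craniotomy) the largest group wins,
  and fellow arcs lying in the same annulus around the hull centroid of
  all candidates are merged back in.  Interior metal (catheters, bolts)
  fails both the enclosure and the annulus test.
* **Centroid.** Centroid of the convex hull of the shell, quantized to
  1/8 px.  The hull keeps the centroid inside the interior under one-sided
  defects; the quantization makes every downstream ray sample — and hence
  the whole pipeline — exactly equivariant under integer translations.
* **Gap detection is angular.** A gap is a maximal circular run of rays
  meeting no bone.  Fracture bridges interpolate the first/last shell
  radius linearly between the gap's flanks.  Mirror sealing reflects each
  open ray across the vertical axis (midline), falling back to the
  horizontal axis; the mirrored radii of each run are anchored to the
  measured radii at the run's flanks, which absorbs the centroid offset a
  one-sided craniotomy induces.  If both mirrors are open the cranium is
  reported unsealable.  Pseudo bridges are painted with enforced radial
  continuity (3-ray min/max window), dilated once 8-connected, and a
  disk-3 closing repairs sub-ray pinholes as a last resort.  Whether the
  original rasterization followed chords or arcs is unknowable; rays were
  chosen for robustness to shell thickness.
* **Connectivity.** 8-connected component labeling, 4-connected flood
  fill — diagonal shell joints must block the fill.
* **Pseudo-cranial pixels are scaffolding**: never counted among retained
  pixels or in any HU statistic.
* **Slices without bone.** A slice with no bone candidates falls back to
  the union of in-bounds components not touching the border.  This makes
  `segment_slice` idempotent on already-segmented slices and still rejects
  empty (all-air) slices.

## Scoring

CES = HU_17^24, mCES = HU_19^23; comparisons are inclusive (≥).  Default
cutoffs 16.03 % (severity), 16.29 % (delayed-edema screening) and 15.27 %
(mortality) are the reference operating points at full precision; the
conflicting figure-caption value 22.58 % for the severity cutoff is
selectable via `ScoreThresholds(ces_cutoff=22.58)` but not defaulted —
the two values cannot be reconciled from the source text.

## Cohort statistics

* Mann-Whitney U: exact enumeration when combined n ≤ 12 without ties;
  otherwise tie-corrected normal approximation **without** continuity
  correction, matching the "asymptotic significance" convention of the
  major commercial packages.  All p-values two-sided.
* Constant pooled samples short-circuit to p = 1 (rank tests are undefined
  there); constant samples are rejected by the Shapiro-Wilk gate.
* Per-bin scans apply no multiple-testing correction across the 80 bins by
  default (Holm step-down behind `holm=True`); discriminative bands are
  maximal contiguous runs of significant bins — the minimal reading of
  reported HU ranges — and the longest band breaks ties toward lower HU.
* ROC curves enumerate every distinct score as a ≥ threshold; AUC is
  trapezoidal and equals the concordance probability (ties half).  "Highest
  predictive power" is operationalized as Youden's J (ties: higher
  specificity, then lower cutoff); closest-to-corner is available via
  `select_cutoff(criterion="closest_to_corner")`.  The J criterion is a
  package choice — the selection rule was not otherwise specified.
* Fisher's exact test replaces the Pearson chi-square on 2×2 tables when
  any expected count is below 5; larger tables always use chi-square.

## Synthetic phantoms

A phantom slice is an elliptical cranial shell (bone ≈ 1000 ± 60 HU,
thickness ≥ 2 px) around a tissue interior, wrapped in scalp
(≈ 45 ± 15 HU, overlapping brain HU deliberately), on an air background,
optionally with: fracture gaps (soft tissue in the gap), craniotomy arcs,
a metal catheter tract (3000 HU, detached from the shell, as the
intraparenchymal portion visible in one plane), an intracranial air bubble
(−1000 HU) and a gantry/head-rest arc touching the image border (geometry
tuned for the default 512 grid).  Interior HU values are drawn from a
discrete three-component mixture: CSF N(8, 4), parenchyma N(29, 4.7),
blood N(55, 8) with weights 0.12/0.85/0.03, truncated and discretized on
0–79.  The parenchymal width 4.7 HU is calibrated so the reference mild
mixture's HU 17–24 mass equals the observed mild-group median CES
(14.31 %); the modes 29 (mild) and 24 (severe) mirror the reported
histogram peaks of surviving vs deceased subjects.  Series scale the
geometry along the vertex→caudal axis by sqrt(1 − z²), z from 0.85 to 0.
All randomness flows from `SeedSequence(seed)` with children spawned in a
fixed (subject, slice) order, so subsets regenerate identically.

### Cohort model

Each subject draws a perturbed mixture: parenchymal mode jitter
N(0, 2.5 HU), width jitter N(0, 1.2 HU), component-weight jitter
N(0, 0.015), independent per-bin lognormal roughness (σ = 0.25), then the
HU 17–24 mass is pinned to the subject's band level b ~ N(group mean,
3.0 pp).  Mild subjects centre on the reference mild band mass (≈ 14.3 %);
severe-type subjects add `band_mass_shift` (default 8 pp, the observed
median CES gap).  The exchanged mass comes from the **parenchymal** share
of each out-of-band bin — edema converts normal parenchyma into
band-density tissue; CSF and blood pools are untouched.  The between-
subject band sd of 3.0 pp makes the default cohort separate with CES AUC
≈ 0.95; the wider overlap of the real cohort (AUC ≈ 0.85) is reproducible
with `ces_sd≈5.5`.  Delayed and deceased subjects use severe parameters
and differ only in label — no separate quantitative description of those
groups' distributions is available, which also means the simulated
mortality contrast is weaker than the real one.  Observed distributions
are multinomial draws of `slices_per_subject × pixels_per_slice` pixels
from the subject pmf.

What the generator does **not** emulate: reconstruction physics (no
sinograms, beam hardening, kernels or noise texture), partial-volume
gradients at tissue boundaries, anatomy (ventricle shapes, gray/white
contrast, age-dependent myelination beyond a mode shift), or
scanner-to-scanner HU drift.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under a known generative
model — not clinical performance on real scans.

### Statistical experiments

The null-calibration and band-recovery experiments sample subject
distributions directly from the cohort model (no image rendering): the
imaging layer is validated separately — exact truth consistency on
artifact-free phantoms, Dice ≥ 0.95 on 50 randomized defect phantoms —
and end-to-end on a reduced rendered cohort, so rerendering inside the
statistical loops would only add Monte-Carlo cost.  Experiment sizes:
50 phantoms for mask recovery, 100 seeds × (30 vs 30 subjects) for null
calibration and band recovery.  In the recovery experiment both groups
share the tissue mode so that the *only* systematic difference is the
+8 pp band shift — with the default unequal modes the groups differ
broadly across HU 10–50 and no single true band exists to recover.
Calibration is judged per bin against the exact central 95 % binomial
interval for 100 draws at α = 0.05 (allowing the handful of bins expected
outside by chance) plus a pooled-rate window of 0.040–0.060; the J clause
is judged on the mean and median across seeds because a single-seed J at
n = 30/30 carries sampling noise of about ±0.1.

## Known limitations

* The sealing heuristics assume one head with a mostly convex shell;
  bilateral symmetric defects are correctly reported unsealable rather
  than guessed at.
* The gantry model and its removal rule assume hardware reaches the image
  border; floating hardware fully inside the field of view would survive
  stage C (though it still cannot enter the sealed interior).
* `categorical_test` offers Fisher's exact only for 2×2 tables.
* Verdicts are threshold classifications of a synthetic-validated score;
  nothing here claims clinical validity on real patients.
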