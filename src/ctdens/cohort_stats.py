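"""Cohort-level statistics for density distributions.

The analysis pipeline mirrors standard nonparametric practice: a
Shapiro-Wilk gate decides against normality, per-HU-bin Mann-Whitney U
tests compare two groups' proportion vectors, maximal contiguous runs of
significant bins form candidate discriminative bands, and an empirical ROC
curve with a Youden-J cutoff turns a band proportion into a classifier.

Conventions
-----------
* All p-values are two-sided.
* Mann-Whitney p is by exact enumeration when the combined sample size is
  at most 12 with no ties, otherwise by the tie-corrected normal
  approximation without continuity correction (the convention of the major
  commercial statistics packages' "asymptotic significance").
* Classification is at >= cutoff: a score equal to the cutoff is positive.
* No multiple-testing correction is applied across the 80 bins by default;
  Holm correction is available behind ``holm=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError

__all__ = [
    "BandScanResult",
    "RocResult",
    "ConfusionSummary",
    "shapiro_wilk_gate",
    "mann_whitney",
    "kruskal_wallis",
    "per_bin_scan",
    "roc_curve",
    "select_cutoff",
    "predictive_values",
    "categorical_test",
    "frequency_table",
]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def shapiro_wilk_gate(samples) -> tuple[str, float]:
    """Shapiro-Wilk normality gate: ``("non_normal", p)`` when p < 0.05.

    A non-normal verdict routes the downstream comparisons to the
    nonparametric path.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 3:
        raise DegenerateSampleError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no distribution to test")
    p = float(stats.shapiro(x).pvalue)
    return ("non_normal" if p < 0.05 else "normal", p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U of sample ``a`` and the two-sided p-value.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    tie-corrected normal approximation (no continuity correction).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size) / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# per-bin scan and band discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandScanResult:
    """Per-bin two-sided p-values and the contiguous significant HU bands."""

    p_values: np.ndarray          # (80,)
    alpha: float
    bands: tuple[tuple[int, int], ...]  # inclusive (lo, hi), disjoint, sorted

    def longest_band(self) -> tuple[int, int] | None:
        """Longest significant band; ties broken toward the lowest HU."""
        if not self.bands:
            return None
        return max(self.bands, key=lambda b: (b[1] - b[0], -b[0]))

    def to_frame(self) -> pd.DataFrame:
        sig = self.p_values < self.alpha
        return pd.DataFrame({"hu": np.arange(self.p_values.size),
                             "p_value": self.p_values,
                             "significant": sig})


def _runs_below(p: np.ndarray, alpha: float) -> tuple[tuple[int, int], ...]:
    sig = p < alpha
    bands, i = [], 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j < sig.size and sig[j]:
                j += 1
            bands.append((i, j - 1))
            i = j
        else:
            i += 1
    return tuple(bands)


def per_bin_scan(group_a: np.ndarray, group_b: np.ndarray,
                 alpha: float = 0.05, holm: bool = False) -> BandScanResult:
    """Mann-Whitney test per HU bin between two subjects-by-80 matrices.

    ``bands`` are the maximal contiguous runs of bins with p < alpha
    (after Holm step-down when ``holm=True``).
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("bin count mismatch")
    p = np.array([mann_whitney(A[:, j], B[:, j])[1] for j in range(A.shape[1])])
    if holm:
        order = np.argsort(p)
        m = p.size
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        p = adj
    return BandScanResult(p_values=p, alpha=alpha, bands=_runs_below(p, alpha))


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve over all distinct score thresholds (>= convention).

    ``points`` runs from (0, 0) — classify nothing positive — down the
    sorted thresholds to (1, 1).  ``thresholds`` aligns with ``points[1:]``.
    """

    points: np.ndarray       # (m, 2) columns fpr, tpr
    thresholds: np.ndarray   # (m-1,) descending score values
    auc: float
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC curve and trapezoidal AUC.

    The AUC equals the concordance probability (ties counted half), i.e.
    U / (n1 * n2) of the positive scores.
    """
    s, y = _check_labels(scores, labels)
    thresholds = np.unique(s)[::-1]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = s >= t
        tpr.append(float((pred & y).sum()) / n_pos)
        fpr.append(float((pred & ~y).sum()) / n_neg)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocResult(points=points, thresholds=thresholds, auc=auc)


def select_cutoff(roc: RocResult, criterion: str = "youden") -> RocResult:
    """Pick the operating point with the highest predictive power.

    ``youden`` maximizes J = sensitivity + specificity - 1; ties break
    toward higher specificity, then toward the lower cutoff.
    ``closest_to_corner`` minimizes the Euclidean distance to (0, 1).
    Returns a copy of ``roc`` with cutoff/sensitivity/specificity filled.
    """
    sens = roc.points[1:, 1]
    spec = 1.0 - roc.points[1:, 0]
    if criterion == "youden":
        score = sens + spec - 1.0
    elif criterion == "closest_to_corner":
        score = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    # lexicographic: max score, then max specificity, then lowest cutoff;
    # thresholds are descending so later index = lower cutoff
    order = sorted(
        range(score.size),
        key=lambda i: (score[i], spec[i], -roc.thresholds[i]),
        reverse=True,
    )
    best = order[0]
    return replace(roc, cutoff=float(roc.thresholds[best]),
                   sensitivity=float(sens[best]), specificity=float(spec[best]))


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and rates at a >= cutoff; undefined rates are None."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def npv(self) -> float | None:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else None


def predictive_values(scores, labels, cutoff: float) -> ConfusionSummary:
    """Confusion summary of the classifier ``score >= cutoff``."""
    s, y = _check_labels(scores, labels)
    pred = s >= cutoff
    return ConfusionSummary(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


# ---------------------------------------------------------------------------
# categorical variables
# ---------------------------------------------------------------------------

def categorical_test(table) -> tuple[float, float, str]:
    """Pearson chi-square or Fisher's exact test on a contingency table.

    For 2x2 tables Fisher's exact test is used when any expected count is
    below 5, otherwise the Pearson chi-square (uncorrected); larger tables
    always use the chi-square.  Returns (statistic, p, method) where the
    statistic is the odds ratio for Fisher and chi-square otherwise.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must be a 2-D grid of nonnegative integer counts")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if t.shape == (2, 2):
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (expected < 5).any():
            odds, p = stats.fisher_exact(t, alternative="two-sided")
            return float(odds), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p), "chi-square"


def frequency_table(labels) -> pd.DataFrame:
    """Counts and percentages of categorical labels (cohort summaries)."""
    ser = pd.Series(list(labels))
    counts = ser.value_counts()
    return pd.DataFrame({
        "count": counts,
        "percent": 100.0 * counts / counts.sum(),
    })
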