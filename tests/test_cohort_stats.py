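"""Nonparametric cohort statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from ctdens.cohort_stats import (
    categorical_test,
    frequency_table,
    kruskal_wallis,
    mann_whitney,
    per_bin_scan,
    predictive_values,
    roc_curve,
    select_cutoff,
    shapiro_wilk_gate,
)
from ctdens.errors import DegenerateSampleError
from ctdens.phantom import CohortSpec, simulate_cohort_distributions


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def mw_u_oracle(a, b):
    """U of sample a by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def mw_exact_p_oracle(a, b):
    """Two-sided exact p by enumeration over all label assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = mw_u_oracle(a, b)
    mu = n_a * len(b) / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mw_u_oracle(grp, rest)
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def fisher_p_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration (sum of tables with
    probability <= observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestShapiroGate:
    def test_uniform_sample_flagged_non_normal(self):
        x = np.random.default_rng(10).uniform(0, 1, 500)
        verdict, p = shapiro_wilk_gate(x)
        assert verdict == "non_normal" and p < 0.05

    def test_normal_sample_passes_for_most_seeds(self):
        passes = 0
        for seed in range(20):
            x = np.random.default_rng(100 + seed).normal(0, 1, 500)
            verdict, _ = shapiro_wilk_gate(x)
            passes += verdict == "normal"
        assert passes >= 17  # expect ~95% at alpha=0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk_gate([3.0] * 10)

    def test_too_small_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk_gate([1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.5], [3.0, 4.0]
        u_a, p_a = mann_whitney(a, b)
        u_b, p_b = mann_whitney(b, a)
        assert u_b == len(a) * len(b) - u_a
        assert p_a == pytest.approx(p_b)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        # tie-free small samples -> exact path
        vals = rng.permutation(12)[: rng.integers(5, 11)]
        k = int(rng.integers(2, len(vals) - 1))
        a, b = vals[:k].tolist(), vals[k:].tolist()
        u, p = mann_whitney(a, b)
        assert u == pytest.approx(mw_u_oracle(a, b))
        assert p == pytest.approx(mw_exact_p_oracle(a, b), abs=1e-12)

    def test_u_statistic_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 6, 40).astype(float)
        b = rng.integers(0, 6, 35).astype(float)
        u, _ = mann_whitney(a, b)
        assert u == pytest.approx(mw_u_oracle(a, b))

    def test_identical_constant_groups(self):
        u, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        g = [1.0, 2.0, 3.0]
        h, p = kruskal_wallis([g, g, g])
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_two_groups_agrees_with_mann_whitney_asymptotically(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.3, 1, 200)
        _, p_kw = kruskal_wallis([a, b])
        _, p_mw = mann_whitney(a, b)
        assert p_kw == pytest.approx(p_mw, rel=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, 25) for m in (0, 0.5, 1.0)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])

    def test_three_simulated_severity_groups_differ(self):
        c = CohortSpec(n_mild=15, n_severe=15, n_delayed=8, n_deceased=0, seed=41)
        X, man = simulate_cohort_distributions(c)
        ces = X[:, 17:25].sum(axis=1)
        groups = [ces[(man.label == g).values] for g in ("mild", "severe", "delayed")]
        _, p = kruskal_wallis(groups)
        assert p < 0.01


class TestPerBinScan:
    def test_alpha_zero_gives_no_bands(self):
        rng = np.random.default_rng(14)
        A, B = rng.random((5, 80)), rng.random((5, 80))
        scan = per_bin_scan(A, B, alpha=0.0)
        assert scan.bands == ()

    def test_bands_are_maximal_contiguous_runs(self):
        rng = np.random.default_rng(15)
        A = rng.normal(0, 1, (12, 80))
        B = rng.normal(0, 1, (12, 80))
        B[:, 30:35] += 5.0  # strong effect in bins 30..34
        scan = per_bin_scan(A, B)
        assert any(lo <= 30 and hi >= 34 for lo, hi in scan.bands)
        for lo, hi in scan.bands:
            assert np.all(scan.p_values[lo:hi + 1] < scan.alpha)
            if lo > 0:
                assert scan.p_values[lo - 1] >= scan.alpha
            if hi < 79:
                assert scan.p_values[hi + 1] >= scan.alpha

    def test_min_group_size_enforced(self):
        with pytest.raises(ValueError):
            per_bin_scan(np.zeros((1, 80)), np.zeros((5, 80)))

    def test_longest_band_tie_breaks_to_lowest_hu(self):
        from ctdens.cohort_stats import BandScanResult
        p = np.ones(80)
        p[10:13] = 0.001
        p[40:43] = 0.001
        scan = BandScanResult(p_values=p, alpha=0.05,
                              bands=((10, 12), (40, 42)))
        assert scan.longest_band() == (10, 12)


class TestRoc:
    def test_perfect_separation(self):
        roc = select_cutoff(roc_curve([1, 2, 3, 10, 11, 12],
                                      [0, 0, 0, 1, 1, 1]))
        assert roc.auc == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_independent_scores_auc_near_half(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(0, 1, 1000)
        labels = rng.random(1000) < 0.5
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_u_over_n1n2(self):
        rng = np.random.default_rng(17)
        scores = rng.permutation(60).astype(float)  # tie-free
        labels = rng.random(60) < 0.4
        roc = roc_curve(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        u, _ = mann_whitney(pos, neg)
        assert roc.auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(18)
        scores = rng.normal(0, 1, 80)
        labels = rng.random(80) < 0.5
        r1 = roc_curve(scores, labels)
        r2 = roc_curve(np.exp(scores), labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert np.allclose(r1.points, r2.points)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(19)
        scores = rng.normal(0, 1, 200) + rng.integers(0, 2, 200)
        labels = rng.random(200) < 0.5
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_curve_monotone(self):
        rng = np.random.default_rng(20)
        roc = roc_curve(rng.normal(0, 1, 50), rng.random(50) < 0.5)
        assert np.all(np.diff(roc.points[:, 0]) >= 0)
        assert np.all(np.diff(roc.points[:, 1]) >= 0)


class TestSelectCutoff:
    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            scores = np.round(rng.normal(0, 1, 40), 2)
            labels = rng.random(40) < 0.45
            if labels.all() or not labels.any():
                continue
            roc = select_cutoff(roc_curve(scores, labels))
            # brute force over every candidate cutoff
            best = None
            for c in np.unique(scores):
                sens = np.mean(scores[labels] >= c)
                spec = np.mean(scores[~labels] < c)
                j = sens + spec - 1
                key = (j, spec, -c)
                if best is None or key > best[0]:
                    best = (key, c, sens, spec)
            assert roc.cutoff == pytest.approx(best[1])
            assert roc.sensitivity == pytest.approx(best[2])
            assert roc.specificity == pytest.approx(best[3])

    def test_degenerate_equal_scores(self):
        roc = select_cutoff(roc_curve([5.0] * 6, [0, 0, 0, 1, 1, 1]))
        assert roc.cutoff == 5.0
        assert roc.sensitivity + roc.specificity - 1 == pytest.approx(0.0)


class TestPredictiveValues:
    def test_perfect_classifier(self):
        cm = predictive_values([1, 2, 9, 10], [0, 0, 1, 1], cutoff=5.0)
        assert cm.ppv == 1.0 and cm.npv == 1.0

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(0, 1, 100)
        labels = rng.random(100) < 0.3
        cutoff = 0.2
        cm = predictive_values(scores, labels, cutoff)
        tp = sum(1 for s, y in zip(scores, labels) if s >= cutoff and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= cutoff and not y)
        tn = sum(1 for s, y in zip(scores, labels) if s < cutoff and not y)
        fn = sum(1 for s, y in zip(scores, labels) if s < cutoff and y)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)

    def test_low_prevalence_gives_high_npv_low_ppv(self):
        # 8 positives among 45 subjects with a weakly informative score
        rng = np.random.default_rng(23)
        labels = np.zeros(45, dtype=bool)
        labels[:8] = True
        scores = rng.normal(0, 1, 45) + 0.8 * labels
        cm = predictive_values(scores, labels, cutoff=0.0)
        assert cm.npv is not None and cm.ppv is not None
        assert cm.npv > cm.ppv

    def test_undefined_rates_are_none(self):
        cm = predictive_values([1, 2], [0, 1], cutoff=10.0)
        assert cm.ppv is None
        assert cm.npv == 0.5


class TestCategorical:
    def test_strong_association(self):
        stat, p, method = categorical_test([[10, 0], [0, 10]])
        assert p < 0.001
        assert method in ("fisher", "chi-square")

    def test_fisher_matches_hypergeometric_enumeration(self):
        for table in ([[3, 1], [1, 3]], [[2, 5], [6, 1]], [[0, 4], [4, 0]]):
            stat, p, method = categorical_test(table)
            assert method == "fisher"
            assert p == pytest.approx(fisher_p_oracle(table), abs=1e-9)

    def test_independence_table(self):
        _, p, _ = categorical_test([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_method_rule_uses_expected_counts(self):
        # large balanced table -> chi-square
        _, _, method = categorical_test([[20, 30], [25, 25]])
        assert method == "chi-square"
        # small table -> fisher
        _, _, method = categorical_test([[2, 3], [3, 2]])
        assert method == "fisher"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [0, 0]])


class TestFrequencyTable:
    def test_counts_and_percentages(self):
        labels = ["a"] * 6 + ["b"] * 64
        tab = frequency_table(labels)
        assert tab.loc["a", "count"] == 6
        assert tab.loc["a", "percent"] == pytest.approx(100 * 6 / 70)
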