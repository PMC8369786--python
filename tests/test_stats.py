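"""Evaluation statistics against independent oracles.

AUC is checked against brute-force O(n^2) pair counting, the Youden cut-off
against exhaustive search, Clopper-Pearson against its closed-form edges and
simulated coverage, Fisher's p against direct hypergeometric enumeration,
the Welch test against a label-permutation test, and ICC(2,1) against both
a variance-component simulation and pingouin's implementation.
"""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ccar.stats import (
    categorical_test,
    clopper_pearson,
    correlation,
    diagnostic_performance,
    empirical_roc,
    format_p,
    icc_interobserver,
    mean_ci,
    two_sample_t,
)

# -- oracles ------------------------------------------------------------------


def auc_pair_counting(scores, labels):
    """P(score_pos < score_neg) + 1/2 P(tie), by explicit pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p < n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Max J over all observed thresholds for the rule 'positive iff score < t'."""
    pos = np.asarray([s for s, y in zip(scores, labels) if y])
    neg = np.asarray([s for s, y in zip(scores, labels) if not y])
    best = -2.0
    for t in np.unique(scores):
        j = (pos < t).mean() + (neg >= t).mean() - 1.0
        best = max(best, j)
    return best


def fisher_two_sided_enumeration(table):
    """Two-sided Fisher p: sum hypergeometric probabilities <= P(observed)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


# -- group tests --------------------------------------------------------------


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_near_complete_separation(self):
        _, p = two_sample_t([0, 0, 0, 0], [10, 10, 10, 10.0001])
        assert p < 0.001

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])

    def test_matches_permutation_oracle(self, rng):
        """Under exchangeable groups the Welch p matches a permutation p."""
        a = rng.normal(50, 12, 25)
        b = rng.normal(50, 12, 27)
        _, p_welch = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        diffs = np.abs(perm[:, :25].mean(axis=1) - perm[:, 25:].mean(axis=1))
        p_perm = (1 + (diffs >= obs).sum()) / (n_perm + 1)
        assert p_welch == pytest.approx(p_perm, abs=0.03)


class TestCategorical:
    def test_independent_table(self):
        stat, p, method = categorical_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert method == "pearson"

    def test_tram_track_pearson_statistic(self):
        # hand computation: 52 * (8*25 - 19*0)^2 / (27 * 25 * 8 * 44) = 8.754
        stat, _, method = categorical_test([[8, 19], [0, 25]], method="pearson")
        assert stat == pytest.approx(8.754, abs=0.005)
        assert method == "pearson"

    def test_sparse_2x2_falls_back_to_fisher(self):
        # bridge-sign table: min expected count 7 * 25 / 52 < 5
        table = [[6, 21], [1, 24]]
        odds, p, method = categorical_test(table)
        assert method == "fisher"
        assert p == pytest.approx(fisher_two_sided_enumeration(table), rel=1e-6)
        assert round(p, 3) == 0.101

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            categorical_test([[1, 0], [2, 0]])


class TestCorrelation:
    def test_known_relationships(self):
        x = np.arange(10.0)
        assert correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlation(x, -x)[0] == pytest.approx(-1.0)
        assert correlation(x, np.exp(x), method="spearman")[0] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlation([1, 1, 1], [1, 2, 3])


# -- ROC ----------------------------------------------------------------------


class TestRoc:
    def test_perfect_separation(self):
        scores = [10, 12, 14, 40, 50, 60]
        labels = [True, True, True, False, False, False]
        roc = empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)
        # the cut-off separates: all positives below, all negatives at/above
        assert max(scores[:3]) < roc.optimal_cutoff <= min(scores[3:])

    def test_all_tied_scores(self):
        roc = empirical_roc([5, 5, 5, 5], [True, False, True, False])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            empirical_roc([1, 2, 3], [True, True, True])

    def test_auc_matches_pair_counting_with_ties(self, rng):
        # 12-point toy set with deliberate ties
        scores = [10, 10, 20, 20, 20, 30, 20, 30, 40, 40, 50, 10]
        labels = [True] * 6 + [False] * 6
        roc = empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(auc_pair_counting(scores, labels))

    def test_oracle_equivalence_random_instances(self, rng):
        """AUC = pair counting and J = exhaustive search on random data."""
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 15, n).astype(float)  # heavy ties
            labels = np.zeros(n, bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            roc = empirical_roc(scores, labels)
            assert roc.auc == pytest.approx(auc_pair_counting(scores, labels))
            assert roc.youden_j == pytest.approx(youden_exhaustive(scores, labels))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(30, 10, 40)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        base = empirical_roc(scores, labels)
        warped = empirical_roc(np.exp(scores / 20.0), labels)
        assert warped.auc == pytest.approx(base.auc)

    def test_delong_ci_brackets_auc(self, rng):
        scores = np.concatenate([rng.normal(22, 12, 27), rng.normal(50, 12, 25)])
        labels = np.array([True] * 27 + [False] * 25)
        roc = empirical_roc(scores, labels)
        lo, hi = roc.auc_ci
        assert lo <= roc.auc <= hi
        assert 0.0 <= lo and hi <= 1.0
        hanley = empirical_roc(scores, labels, ci_method="hanley")
        assert hanley.auc == pytest.approx(roc.auc)
        assert hanley.auc_ci != roc.auc_ci

    def test_tie_break_prefers_higher_sensitivity_then_lower_threshold(self):
        roc = empirical_roc([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        # J = 1 at thresholds 3 (sens 1) and also J from 2.0 lower; max J unique here
        maximizers = []
        pos, neg = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        for t in [1.0, 2.0, 3.0, 4.0]:
            j = (pos < t).mean() + (neg >= t).mean() - 1
            maximizers.append((t, j, (pos < t).mean()))
        best_j = max(j for _, j, _ in maximizers)
        best_sens = max(s for _, j, s in maximizers if j == best_j)
        expected = min(t for t, j, s in maximizers if j == best_j and s == best_sens)
        assert roc.optimal_cutoff == expected


class TestDiagnosticPerformance:
    def test_perfect_classifier(self):
        perf = diagnostic_performance([1, 2, 8, 9], [True, True, False, False], cutoff=5.0)
        assert perf.sensitivity.estimate == 1.0
        assert perf.specificity.estimate == 1.0
        assert perf.accuracy.estimate == 1.0

    def test_cutoff_below_all_scores(self):
        perf = diagnostic_performance([5, 6, 7, 8], [True, False, True, False], cutoff=1.0)
        assert perf.sensitivity.estimate == 0.0
        assert perf.specificity.estimate == 1.0

    def test_counts_partition_classes(self, rng):
        scores = rng.normal(35, 15, 52)
        labels = rng.random(52) < 0.5
        labels[:2] = [True, False]
        perf = diagnostic_performance(scores, labels, cutoff=36.4)
        assert perf.tp + perf.fn == labels.sum()
        assert perf.tn + perf.fp == (~labels).sum()
        # confusion-matrix oracle
        tp = sum(1 for s, y in zip(scores, labels) if y and s < 36.4)
        tn = sum(1 for s, y in zip(scores, labels) if not y and s >= 36.4)
        assert perf.accuracy.estimate == pytest.approx((tp + tn) / 52)
        for prop in (perf.sensitivity, perf.specificity, perf.accuracy):
            assert prop.ci[0] <= prop.estimate <= prop.ci[1]


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, expected_lower",
        [(10, 10, 0.025 ** (1 / 10)), (16, 16, 0.025 ** (1 / 16))],
    )
    def test_closed_form_at_full_successes(self, x, n, expected_lower):
        lo, hi = clopper_pearson(x, n)
        assert lo == pytest.approx(expected_lower, abs=1e-10)
        assert hi == 1.0

    def test_closed_form_at_zero_successes(self):
        lo, hi = clopper_pearson(0, 20)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-10)

    def test_printed_floor_values(self):
        # the exact CI floors at 10/10 and 16/16 successes, as percentages
        assert round(100 * clopper_pearson(10, 10)[0], 1) == 69.2
        assert round(100 * clopper_pearson(16, 16)[0], 1) == 79.4

    def test_coverage_at_least_nominal(self, rng):
        n, p_true = 25, 0.3
        bounds = np.array([clopper_pearson(x, n) for x in range(n + 1)])
        draws = rng.binomial(n, p_true, 10_000)
        covered = (bounds[draws, 0] <= p_true) & (p_true <= bounds[draws, 1])
        assert covered.mean() >= 0.95  # exact interval is conservative

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


# -- ICC ----------------------------------------------------------------------


class TestIcc:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_interobserver(x)
        assert res.icc == pytest.approx(1.0)
        assert res.ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_absolute_agreement_penalizes_offset(self, rng):
        subj = rng.normal(0, 1, 30)
        x = np.column_stack([subj, subj + 10.0])  # huge systematic offset
        res = icc_interobserver(x)
        assert res.icc < 0.5
        # consistency ICC(3,1) oracle ignores the offset entirely
        n, k = x.shape
        grand, rm, cm = x.mean(), x.mean(axis=1), x.mean(axis=0)
        msr = k * ((rm - grand) ** 2).sum() / (n - 1)
        mse = ((x - rm[:, None] - cm[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc < icc_consistency - 0.4

    def test_recovers_variance_components(self, rng):
        # sigma_subject^2 = 9 * sigma_error^2 -> true ICC = 0.9
        n = 200
        subj = rng.normal(0, 3.0, n)
        x = subj[:, None] + rng.normal(0, 1.0, (n, 2))
        res = icc_interobserver(x)
        assert res.icc == pytest.approx(0.9, abs=0.05)
        assert res.ci[0] <= 0.9 <= res.ci[1] or abs(res.icc - 0.9) < 0.02

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        x = rng.normal(0, 2, n)[:, None] + rng.normal(0, 1, (n, 3))
        res = icc_interobserver(x)
        long = pd.DataFrame(
            {
                "t": np.repeat(np.arange(n), 3),
                "r": np.tile(["a", "b", "c"], n),
                "y": x.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="t", raters="r", ratings="y")
        row = table.set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert res.ci[0] == pytest.approx(row["CI95"][0], abs=0.006)
        assert res.ci[1] == pytest.approx(row["CI95"][1], abs=0.006)

    def test_degenerate_no_subject_variance(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = icc_interobserver(np.full((6, 2), 3.0))
        assert math.isnan(res.icc)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_interobserver(np.zeros((4, 2)))  # too few subjects
        with pytest.raises(ValueError):
            icc_interobserver(np.zeros((10, 1)))  # one rater


class TestMeanCi:
    def test_constant_sample(self):
        mean, sd, lo, hi = mean_ci([5, 5, 5, 5])
        assert (mean, sd) == (5.0, 0.0)
        assert (lo, hi) == (5.0, 5.0)

    def test_closed_form_small_sample(self):
        mean, sd, _, _ = mean_ci([1, 2, 3, 4, 5])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2.5))

    def test_half_width_matches_t_quantile(self, rng):
        # n = 25 with sample mean 50 and sd 11.75: half-width = t * sd / 5
        raw = rng.normal(0, 1, 25)
        sample = 50.0 + 11.75 * (raw - raw.mean()) / raw.std(ddof=1)
        mean, sd, lo, hi = mean_ci(sample)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(11.75)
        assert (hi - lo) / 2 == pytest.approx(sps.t.ppf(0.975, 24) * 11.75 / 5, abs=1e-9)
        assert (hi - lo) / 2 == pytest.approx(4.85, abs=0.01)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


def test_format_p_floor():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.004387) == "0.004"
    assert format_p(0.101) == "0.101"
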