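"""Evaluation statistics for diagnostic cut-off studies.

Group comparison (Welch t, chi-square with Fisher fallback), correlation,
empirical ROC with DeLong AUC confidence intervals and Youden-optimal
cut-off selection, diagnostic performance at a fixed cut-off with exact
Clopper-Pearson intervals, inter-observer ICC(2,1), and mean +/- t-based CI
summaries.

Scores here are the CCAR percents; unless stated otherwise the positivity
convention is "lower score => positive" (a smaller CSF reserve indicates
disease), made explicit through the ``direction`` argument.  Proportions
(sensitivity, specificity, accuracy, AUC) are returned on the [0, 1] scale;
report-level code converts to percent for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "DiagnosticPerformance",
    "ProportionCI",
    "IccResult",
    "two_sample_t",
    "categorical_test",
    "correlation",
    "empirical_roc",
    "diagnostic_performance",
    "clopper_pearson",
    "icc_interobserver",
    "mean_ci",
    "format_p",
]


def format_p(p: float, decimals: int = 3) -> str:
    """p to 3 decimals with a display floor: values below 0.001 print as '<0.001'."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


# -- group tests and correlation ---------------------------------------------


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns (statistic, p).  Welch is the default because equal group
    variances are never guaranteed in observational cohorts; with similar
    group spreads it coincides closely with Student's t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >=2 values, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    # identical degenerate groups: scipy returns nan; the difference is exactly 0
    if np.isnan(t) and np.allclose(a.mean(), b.mean()):
        return 0.0, 1.0
    return float(t), float(p)


def categorical_test(table, method: str = "auto") -> tuple[float, float, str]:
    """Pearson chi-square on a 2 x k contingency table, Fisher fallback for 2 x 2.

    Pearson's statistic is computed without continuity correction.  With
    ``method='auto'`` a 2 x 2 table with any expected cell count below 5
    switches to Fisher's exact test (two-sided); the returned method label
    says which test ran.  ``method='pearson'`` or ``'fisher'`` forces the
    choice.  Returns (statistic, p, method), where the statistic is the
    chi-square value or, for Fisher, the sample odds ratio.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2-D table with >=2 rows and columns, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(np.int64)
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has an empty row or column")
    if method not in ("auto", "pearson", "fisher"):
        raise ValueError(f"method must be 'auto', 'pearson' or 'fisher', got {method!r}")
    expected = sps.contingency.expected_freq(t)
    use_fisher = method == "fisher" or (
        method == "auto" and t.shape == (2, 2) and (expected < 5).any()
    )
    if use_fisher:
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2 x 2 table")
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return float(odds), float(p), "fisher"
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), "pearson"


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


# -- ROC / AUC ----------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC CI and Youden-optimal cut-off.

    ``thresholds`` are the sorted observed score values plus a trailing
    +inf so the curve reaches sensitivity 1; ``sensitivity[i]`` and
    ``specificity[i]`` are the operating point of the rule "positive iff
    score < thresholds[i]" (for direction='lower_is_positive').
    ``optimal_cutoff`` is the observed score value maximizing Youden's
    J = sensitivity + specificity - 1, ties broken toward higher
    sensitivity and then the lower threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float
    youden_j: float
    direction: str
    n_pos: int
    n_neg: int
    ci_method: str = "delong"


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values, orientation 'higher value => positive'.

    v10[i] = fraction of negatives below pos[i] (ties count half);
    v01[j] = fraction of positives above neg[j] (ties count half).
    """
    m, n = pos.size, neg.size
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01


def empirical_roc(
    scores,
    labels,
    direction: str = "lower_is_positive",
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> RocResult:
    """Threshold sweep over observed scores; AUC with CI; Youden cut-off.

    The AUC equals the Mann-Whitney probability that a positive case scores
    on the "diseased" side of a negative case, ties counting one half.  The
    default CI is DeLong's (asymptotic, based on placement variances);
    ``ci_method='hanley'`` selects the Hanley-McNeil exponential
    approximation instead.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size != y.size:
        raise ValueError("scores and labels must align")
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    if y.all() or not y.any():
        raise ValueError("degenerate labels: both classes must be present")
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")

    # orient so that larger oriented score = more positive
    oriented = -s if direction == "lower_is_positive" else s
    pos, neg = oriented[y], oriented[~y]
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())

    m, n = pos.size, neg.size
    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
            np.var(v01, ddof=1) / n if n > 1 else 0.0
        )
        se = float(np.sqrt(var))
    elif ci_method == "hanley":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        se = float(
            np.sqrt(
                (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
            )
        )
    else:
        raise ValueError(f"ci_method must be 'delong' or 'hanley', got {ci_method!r}")
    z = sps.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    # sweep on the original score scale
    thr = np.unique(s)
    if direction == "lower_is_positive":
        sens = np.array([(s[y] < t).mean() for t in thr] + [1.0])
        spec = np.array([(s[~y] >= t).mean() for t in thr] + [0.0])
    else:
        sens = np.array([(s[y] > t).mean() for t in thr[::-1]] + [1.0])
        spec = np.array([(s[~y] <= t).mean() for t in thr[::-1]] + [0.0])
        thr = thr[::-1]
    sweep_thr = np.append(thr, np.inf if direction == "lower_is_positive" else -np.inf)

    # Youden-optimal cut-off restricted to observed values (a reportable
    # operating point); ties -> higher sensitivity, then lower threshold
    j = sens[:-1] + spec[:-1] - 1.0
    order = np.lexsort((thr if direction == "lower_is_positive" else -thr, -sens[:-1], -j))
    best = order[0]
    return RocResult(
        thresholds=sweep_thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        optimal_cutoff=float(thr[best]),
        youden_j=float(j[best]),
        direction=direction,
        n_pos=m,
        n_neg=n,
        ci_method=ci_method,
    )


# -- exact binomial CI and diagnostic performance -----------------------------


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI by inverting the binomial CDF.

    Computed from beta-distribution quantiles; the edges have closed forms:
    at x = 0 the lower bound is 0 and the upper bound 1 - (alpha/2)^(1/n);
    at x = n the lower bound is (alpha/2)^(1/n) and the upper bound 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its exact 95% CI and defining counts."""

    estimate: float
    ci: tuple[float, float]
    successes: int
    n: int


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion-matrix summary of a cut-off rule with exact CIs.

    Accuracy is the "diagnostic coincidence rate": (TP + TN) / N.
    """

    sensitivity: ProportionCI
    specificity: ProportionCI
    accuracy: ProportionCI
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float


def _proportion(successes: int, n: int, alpha: float) -> ProportionCI:
    return ProportionCI(
        estimate=successes / n,
        ci=clopper_pearson(successes, n, alpha),
        successes=successes,
        n=n,
    )


def diagnostic_performance(
    scores,
    labels,
    cutoff: float,
    direction: str = "lower_is_positive",
    alpha: float = 0.05,
) -> DiagnosticPerformance:
    """Sensitivity/specificity/accuracy of "positive iff score < cutoff".

    Exact Clopper-Pearson 95% CIs accompany each proportion, computed from
    the actual counts of the cohort analysed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("degenerate labels: both classes must be present")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = s < cutoff if direction == "lower_is_positive" else s > cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return DiagnosticPerformance(
        sensitivity=_proportion(tp, tp + fn, alpha),
        specificity=_proportion(tn, tn + fp, alpha),
        accuracy=_proportion(tp + tn, s.size, alpha),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        cutoff=float(cutoff),
    )


# -- inter-observer reliability -----------------------------------------------


@dataclass(frozen=True)
class IccResult:
    """Single-rater intraclass correlation with its 95% CI.

    ``model`` records the ICC form so the output is self-describing.
    """

    icc: float
    ci: tuple[float, float]
    model: str = "ICC(2,1) two-way random, absolute agreement, single rater"
    f_value: float = field(default=float("nan"))
    p_value: float = field(default=float("nan"))


def icc_interobserver(measurements, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is a subjects x raters matrix with no missing cells.
    The absolute-agreement form penalizes systematic between-observer
    offsets, which consistency ICCs ignore.  The CI uses the F-distribution
    interval of McGraw & Wong (the standard large-sample form for case 2A).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >=5 subjects and >=2 raters, got {n} x {k}")
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, mse) and np.isclose(msr, 0):
        warnings.warn("degenerate ICC: no between-subject variance", stacklevel=2)
        return IccResult(icc=float("nan"), ci=(float("nan"), float("nan")))
    icc = float((msr - mse) / denom)

    if mse == 0.0:
        # perfect agreement: the F interval is undefined but the ICC is exact
        return IccResult(icc=icc, ci=(icc, icc), f_value=float("inf"), p_value=0.0)

    f_value = msr / mse
    p_value = float(sps.f.sf(f_value, n - 1, (n - 1) * (k - 1)))
    fj = msc / mse
    vn = (n - 1) * (k - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_upper = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_upper * mse) / (f_upper * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_lower * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    return IccResult(icc=icc, ci=(float(lo), float(hi)), f_value=float(f_value), p_value=p_value)


# -- descriptive summaries ----------------------------------------------------


def mean_ci(values, alpha: float = 0.05) -> tuple[float, float, float, float]:
    """Sample mean, SD, and t-based 95% CI: mean +/- t_{n-1} * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = sps.t.ppf(1 - alpha / 2, v.size - 1) * sd / np.sqrt(v.size)
    return mean, sd, mean - half, mean + half
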