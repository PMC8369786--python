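"""Full-cohort analysis: group tables, ROC analyses, ICC, and a JSON report.

``run_full_analysis`` chains every evaluation stage on a validated cohort:

* demographic / neurological group comparison (Welch t, chi-square),
* radiographic-sign and Sato-type tables with CCAR group summaries,
* ROC for intraoperative dural ossification (lower CCAR = positive) with
  DeLong AUC CI and the Youden-optimal cut-off,
* ROC for the dichotomized recovery outcome (recovery rate below the
  good-recovery threshold = positive), plus CCAR-RR correlations,
* diagnostic-performance tables at the published cut-offs with exact
  Clopper-Pearson CIs, and
* inter-observer ICC(2,1) on each observer's end-to-end CCAR.

The report is a plain JSON-serializable dict; regeneration on the same
input and configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import scores, stats
from .io import CohortTable, observer_score_matrix, score_cohort

__all__ = ["AnalysisConfig", "run_full_analysis", "report_to_json", "report_to_markdown",
           "roc_curve_frame"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis knobs, echoed verbatim into every report for provenance."""

    do_cutoffs_pct: tuple[float, ...] = (
        scores.DO_ZONE_UPPER_PCT,
        scores.DO_CUTOFF_PCT,
        scores.NON_DO_ZONE_LOWER_PCT,
    )
    outcome_cutoffs_pct: tuple[float, ...] = (
        scores.DO_ZONE_UPPER_PCT,
        scores.OUTCOME_CUTOFF_PCT,
        scores.GOOD_OUTCOME_LOWER_PCT,
    )
    # recovery dichotomy: RR >= this percent counts as good-or-excellent;
    # the outcome ROC treats RR below it as the positive class
    rr_good_threshold_pct: float = 50.0
    auc_ci_method: str = "delong"
    seed: int | None = None


def _prop_dict(p: stats.ProportionCI) -> dict:
    return {
        "estimate_pct": 100 * p.estimate,
        "ci95_pct": [100 * p.ci[0], 100 * p.ci[1]],
        "successes": p.successes,
        "n": p.n,
    }


def _perf_dict(perf: stats.DiagnosticPerformance) -> dict:
    return {
        "cutoff_pct": perf.cutoff,
        "sensitivity": _prop_dict(perf.sensitivity),
        "specificity": _prop_dict(perf.specificity),
        "diagnostic_coincidence_rate": _prop_dict(perf.accuracy),
        "counts": {"tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn},
    }


def _roc_dict(roc: stats.RocResult) -> dict:
    return {
        "auc": roc.auc,
        "auc_ci95": list(roc.auc_ci),
        "ci_method": roc.ci_method,
        "optimal_cutoff_pct": roc.optimal_cutoff,
        "youden_j": roc.youden_j,
        "direction": roc.direction,
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
    }


def roc_curve_frame(roc: stats.RocResult) -> pd.DataFrame:
    """ROC sweep as a (threshold, sensitivity, specificity) table for CSV export."""
    return pd.DataFrame(
        {
            "threshold_pct": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )


def _group_mean_entry(values) -> dict:
    mean, sd, lo, hi = stats.mean_ci(values)
    return {"mean": mean, "sd": sd, "ci95": [lo, hi], "n": int(len(values))}


def _continuous_comparison(scored: pd.DataFrame, column: str) -> dict:
    a = scored.loc[scored["do_status"], column].dropna().to_numpy()
    b = scored.loc[~scored["do_status"], column].dropna().to_numpy()
    t, p = stats.two_sample_t(a, b)
    return {
        "do": _group_mean_entry(a),
        "nondo": _group_mean_entry(b),
        "t": t,
        "p": p,
        "p_display": stats.format_p(p),
    }


def _categorical_comparison(scored: pd.DataFrame, column: str, categories) -> dict:
    counts = []
    for is_do in (True, False):
        sub = scored.loc[scored["do_status"] == is_do, column]
        counts.append([int((sub == c).sum()) for c in categories])
    table = np.asarray(counts)
    entry = {
        "categories": list(categories),
        "counts_do": counts[0],
        "counts_nondo": counts[1],
    }
    try:
        stat, p, method = stats.categorical_test(table)
        entry.update({"statistic": stat, "p": p, "p_display": stats.format_p(p), "method": method})
    except ValueError as exc:  # e.g. a sign absent in both groups
        entry.update({"statistic": None, "p": None, "method": f"not testable: {exc}"})
    return entry


def run_full_analysis(table: CohortTable | list, config: AnalysisConfig | None = None) -> dict:
    """Score every patient and compute all evaluation statistics.

    Requires both DO classes in the cohort.  Patients whose recovery rate
    is undefined (pre-operative mJOA already maximal) are excluded from RR
    summaries and from the outcome ROC.
    """
    if config is None:
        config = AnalysisConfig()
    scored = score_cohort(table)
    records = table.records if isinstance(table, CohortTable) else tuple(table)
    do_labels = scored["do_status"].to_numpy(dtype=bool)
    if do_labels.all() or not do_labels.any():
        raise ValueError("degenerate cohort: both DO classes required")
    ccar = scored["ccar_pct"].to_numpy(dtype=float)

    # -- group-comparison table (demographics + neurological outcome)
    table1 = {
        "n": {"do": int(do_labels.sum()), "nondo": int((~do_labels).sum())},
        "sex": _categorical_comparison(scored, "sex", ("M", "F")),
        "age_yr": _continuous_comparison(scored, "age_yr"),
        "followup_yr": _continuous_comparison(scored, "followup_yr"),
        "segment": _categorical_comparison(scored, "segment", ("T1-T4", "T5-T8", "T9-T12")),
        "mjoa_pre": _continuous_comparison(scored, "mjoa_pre"),
        "mjoa_followup": _continuous_comparison(scored, "mjoa_followup"),
        "rr_pct": _continuous_comparison(scored, "rr_pct"),
    }

    # -- radiographic features table
    table2 = {
        "sato": _categorical_comparison(
            scored, "sato_type", ("lateral", "extended", "enlarged", "fused", "tuberous")
        ),
        "ccar_pct": _continuous_comparison(scored, "ccar_pct"),
    }
    for sign in ("tts", "cs", "bs"):
        present = scored[sign].astype(bool)
        do_pos = int((present & scored["do_status"]).sum())
        do_neg = int((~present & scored["do_status"]).sum())
        non_pos = int((present & ~scored["do_status"]).sum())
        non_neg = int((~present & ~scored["do_status"]).sum())
        entry = {"counts": {"do_pos": do_pos, "do_neg": do_neg,
                            "nondo_pos": non_pos, "nondo_neg": non_neg}}
        try:
            stat, p, method = stats.categorical_test([[do_pos, do_neg], [non_pos, non_neg]])
            entry.update({"statistic": stat, "p": p,
                          "p_display": stats.format_p(p), "method": method})
        except ValueError as exc:
            entry.update({"statistic": None, "p": None, "method": f"not testable: {exc}"})
        table2[sign] = entry

    # -- DO diagnosis: ROC + performance at the configured cut-offs
    roc_do = stats.empirical_roc(ccar, do_labels, ci_method=config.auc_ci_method)
    table3 = [
        _perf_dict(stats.diagnostic_performance(ccar, do_labels, c))
        for c in config.do_cutoffs_pct
    ]

    # -- recovery outcome: dichotomize RR, ROC + performance table
    rr = scored["rr_pct"].to_numpy(dtype=float)
    defined = np.isfinite(rr)
    poor_outcome = rr[defined] < config.rr_good_threshold_pct
    outcome_block: dict = {"rr_good_threshold_pct": config.rr_good_threshold_pct,
                           "n_defined_rr": int(defined.sum())}
    if poor_outcome.any() and not poor_outcome.all():
        roc_outcome = stats.empirical_roc(
            ccar[defined], poor_outcome, ci_method=config.auc_ci_method
        )
        outcome_block["roc"] = _roc_dict(roc_outcome)
        outcome_block["performance"] = [
            _perf_dict(stats.diagnostic_performance(ccar[defined], poor_outcome, c))
            for c in config.outcome_cutoffs_pct
        ]
    else:
        roc_outcome = None
        outcome_block["roc"] = None
        outcome_block["performance"] = None
        outcome_block["note"] = "outcome labels degenerate; ROC skipped"

    # -- CCAR-RR / CCAR-DO association
    correlations = {}
    if defined.sum() >= 3:
        for method in ("pearson", "spearman"):
            r, p = stats.correlation(ccar[defined], rr[defined], method=method)
            correlations[f"ccar_rr_{method}"] = {"r": r, "p": p, "p_display": stats.format_p(p)}
    r, p = stats.correlation(ccar, do_labels.astype(float), method="spearman")
    correlations["ccar_do_spearman"] = {"r": r, "p": p, "p_display": stats.format_p(p)}

    # -- inter-observer reliability on end-to-end CCAR
    icc = stats.icc_interobserver(observer_score_matrix(records))

    report = {
        "config": {
            **asdict(config),
            "do_cutoffs_pct": list(config.do_cutoffs_pct),
            "outcome_cutoffs_pct": list(config.outcome_cutoffs_pct),
        },
        "n_patients": int(len(scored)),
        "n_ccar_out_of_range": int(scored["ccar_out_of_range"].sum()),
        "group_comparison": table1,
        "radiographic_features": table2,
        "do_roc": _roc_dict(roc_do),
        "do_performance": table3,
        "outcome_analysis": outcome_block,
        "correlations": correlations,
        "interobserver_icc": {
            "icc": icc.icc,
            "ci95": list(icc.ci),
            "model": icc.model,
        },
        "zone_counts": {
            zone: int((scored["ccar_zone"] == zone).sum())
            for zone in ("do_zone", "gray_zone", "non_do_zone")
        },
    }
    report["_roc_objects"] = {"do": roc_do, "outcome": roc_outcome}  # not serialized
    return report


def report_to_json(report: dict, path: str | Path | None = None) -> str:
    """Serialize the report deterministically (sorted keys, fixed format)."""
    payload = {k: v for k, v in report.items() if not k.startswith("_")}
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _fmt_prop(d: dict) -> str:
    lo, hi = d["ci95_pct"]
    return f"{d['estimate_pct']:.1f}% ({lo:.1f} to {hi:.1f}%)"


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of the main report blocks."""
    lines = ["# CCAR analysis report", ""]
    t1 = report["group_comparison"]
    lines += [
        f"Patients: {report['n_patients']} "
        f"(DO {t1['n']['do']}, non-DO {t1['n']['nondo']})",
        "",
        "## CCAR by group",
    ]
    c = report["radiographic_features"]["ccar_pct"]
    for grp in ("do", "nondo"):
        g = c[grp]
        lines.append(
            f"- {grp}: {g['mean']:.1f}% (95% CI {g['ci95'][0]:.1f} to {g['ci95'][1]:.1f}), n={g['n']}"
        )
    lines.append(f"- Welch t p = {c['p_display']}")
    lines += ["", "## DO diagnosis (lower CCAR = positive)"]
    roc = report["do_roc"]
    lines.append(
        f"- AUC = {roc['auc']:.3f} (95% CI {roc['auc_ci95'][0]:.3f} to {roc['auc_ci95'][1]:.3f}), "
        f"optimal cut-off {roc['optimal_cutoff_pct']:.1f}% (J = {roc['youden_j']:.3f})"
    )
    lines.append("")
    lines.append("| cut-off | sensitivity | specificity | coincidence rate |")
    lines.append("|---|---|---|---|")
    for row in report["do_performance"]:
        lines.append(
            f"| < {row['cutoff_pct']:.1f}% | {_fmt_prop(row['sensitivity'])} | "
            f"{_fmt_prop(row['specificity'])} | {_fmt_prop(row['diagnostic_coincidence_rate'])} |"
        )
    out = report["outcome_analysis"]
    lines += ["", "## Recovery outcome"]
    if out["roc"] is not None:
        r = out["roc"]
        lines.append(
            f"- AUC = {r['auc']:.3f} (95% CI {r['auc_ci95'][0]:.3f} to {r['auc_ci95'][1]:.3f}), "
            f"optimal cut-off {r['optimal_cutoff_pct']:.1f}%"
        )
    icc = report["interobserver_icc"]
    lines += [
        "",
        "## Inter-observer reliability",
        f"- ICC = {icc['icc']:.3f} (95% CI {icc['ci95'][0]:.3f} to {icc['ci95'][1]:.3f})",
        f"- model: {icc['model']}",
        "",
    ]
    return "\n".join(lines)
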