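"""CCAR scoring: occupancy ratios, recovery rate, grading, and zones.

The cerebrospinal-fluid cross-section area ratio (CCAR) is measured
indirectly.  On CT the ossified mass is expressed as a fraction of the bony
canal (OCAR); on MRI the cord at the narrowest level is expressed as a
fraction of the reference dural-sac area (SCAR, with the reference taken as
the mean sac area of the adjacent upper and lower levels).  The CSF fraction
is then whatever the mass and the cord do not occupy:

    OCAR = 100 * mass / canal
    SCAR = 100 * cord / sac_ref
    CCAR = 100 - OCAR - SCAR

All ratios are carried as percents (fraction accessors: divide by 100).
Neurological outcome uses the 11-point thoracic mJOA scale and the recovery
rate RR = 100 * (followup - pre) / (11 - pre), graded on the conventional
four-level excellent/good/fair/poor scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "MjoaPair",
    "ScoreInputs",
    "ScorePanel",
    "RrGrade",
    "CcarZone",
    "OutcomeZone",
    "DO_CUTOFF_PCT",
    "DO_ZONE_UPPER_PCT",
    "NON_DO_ZONE_LOWER_PCT",
    "OUTCOME_CUTOFF_PCT",
    "GOOD_OUTCOME_LOWER_PCT",
    "ocar",
    "scar",
    "ccar",
    "recovery_rate",
    "grade_rr",
    "ccar_zone",
    "predict_do",
    "outcome_zone",
    "score_panel",
]

MJOA_MAX = 11

# Published cut-offs (percent CCAR); parameters with these defaults, not
# constants the package tries to re-derive.
DO_CUTOFF_PCT = 36.4          # Youden-optimal cut-off for dural ossification
DO_ZONE_UPPER_PCT = 14.3      # at or below: every patient had DO
NON_DO_ZONE_LOWER_PCT = 44.5  # at or above: no patient had DO
OUTCOME_CUTOFF_PCT = 42.7     # Youden-optimal cut-off for recovery outcome
GOOD_OUTCOME_LOWER_PCT = 45.2  # at or above: recovery good or excellent


class RrGrade(str, Enum):
    POOR = "poor"
    FAIR = "fair"
    GOOD = "good"
    EXCELLENT = "excellent"


class CcarZone(str, Enum):
    DO_ZONE = "do_zone"
    GRAY_ZONE = "gray_zone"
    NON_DO_ZONE = "non_do_zone"


class OutcomeZone(str, Enum):
    POOR_OR_FAIR = "poor_or_fair"
    INDETERMINATE = "indeterminate"
    GOOD_OR_EXCELLENT = "good_or_excellent"


@dataclass(frozen=True)
class MjoaPair:
    """Pre-operative and last-follow-up mJOA scores (integers on 0..11).

    Half-point entries are rejected: the thoracic scale is an 11-point
    integer scale.
    """

    pre: int
    followup: int

    def __post_init__(self) -> None:
        for name, v in (("pre", self.pre), ("followup", self.followup)):
            if not (isinstance(v, int) and not isinstance(v, bool)):
                raise ValueError(f"mJOA {name} must be an integer, got {v!r}")
            if not 0 <= v <= MJOA_MAX:
                raise ValueError(f"mJOA {name} must be in [0, {MJOA_MAX}], got {v}")


@dataclass(frozen=True)
class ScoreInputs:
    """The four averaged areas (mm^2) entering the ratio formulas."""

    canal_area: float
    mass_area: float
    dural_sac_ref_area: float
    cord_area: float

    def __post_init__(self) -> None:
        if self.canal_area <= 0:
            raise ValueError(f"canal_area must be > 0, got {self.canal_area}")
        if self.dural_sac_ref_area <= 0:
            raise ValueError(f"dural_sac_ref_area must be > 0, got {self.dural_sac_ref_area}")
        if self.mass_area < 0 or self.cord_area < 0:
            raise ValueError("areas must be >= 0")


@dataclass(frozen=True)
class ScorePanel:
    """All derived scores for one patient.

    ``ccar`` satisfies ccar = 100 - ocar - scar exactly (never clipped);
    values outside [0, 100], possible under measurement noise, are flagged
    via ``ccar_out_of_range`` and retained.  ``rr`` is None when the
    pre-operative mJOA is already maximal (the recovery rate is undefined),
    and such patients are excluded from aggregate RR statistics.
    """

    ocar: float
    scar: float
    ccar: float
    ccar_out_of_range: bool
    rr: float | None
    rr_grade: RrGrade | None
    ccar_zone: CcarZone
    outcome_zone: OutcomeZone

    @property
    def ccar_fraction(self) -> float:
        return self.ccar / 100.0


def ocar(mass_area: float, canal_area: float) -> float:
    """Ossified-mass occupancy of the bony canal, percent."""
    if canal_area <= 0:
        raise ZeroDivisionError(f"canal_area must be > 0, got {canal_area}")
    if mass_area < 0:
        raise ValueError(f"mass_area must be >= 0, got {mass_area}")
    return 100.0 * mass_area / canal_area


def scar(cord_area: float, dural_sac_ref_area: float) -> float:
    """Cord occupancy of the reference dural sac, percent."""
    if dural_sac_ref_area <= 0:
        raise ZeroDivisionError(f"dural_sac_ref_area must be > 0, got {dural_sac_ref_area}")
    if cord_area < 0:
        raise ValueError(f"cord_area must be >= 0, got {cord_area}")
    return 100.0 * cord_area / dural_sac_ref_area


def ccar(ocar_pct: float, scar_pct: float) -> float:
    """CSF occupancy: 100 - OCAR - SCAR, percent.

    May fall outside [0, 100] when the two ratios come from noisy or
    inconsistent measurements; callers flag (not clip) such values — see
    :func:`score_panel`.
    """
    if ocar_pct < 0 or scar_pct < 0:
        raise ValueError("OCAR and SCAR must be >= 0")
    return 100.0 - ocar_pct - scar_pct


def recovery_rate(scores: MjoaPair) -> float | None:
    """Neurological recovery rate, percent of the achievable improvement.

    RR = 100 * (followup - pre) / (11 - pre).  Undefined (None) when
    pre = 11: no improvement is achievable.  Negative values indicate
    post-operative deterioration.
    """
    if scores.pre == MJOA_MAX:
        return None
    return 100.0 * (scores.followup - scores.pre) / (MJOA_MAX - scores.pre)


def grade_rr(rr: float | None) -> RrGrade | None:
    """Four-level recovery grade: >=75 excellent, >=50 good, >=25 fair, else poor.

    Applied to the unrounded RR.  A negative RR (deterioration) maps to
    poor, the scale's worst category.  None (undefined RR) propagates.
    """
    if rr is None:
        return None
    if math.isnan(rr):
        raise ValueError("rr is NaN")
    if rr >= 75:
        return RrGrade.EXCELLENT
    if rr >= 50:
        return RrGrade.GOOD
    if rr >= 25:
        return RrGrade.FAIR
    return RrGrade.POOR


def ccar_zone(
    ccar_pct: float,
    do_zone_upper: float = DO_ZONE_UPPER_PCT,
    non_do_zone_lower: float = NON_DO_ZONE_LOWER_PCT,
) -> CcarZone:
    """Three-zone DO classification: <=14.3 DO zone, >=44.5 non-DO zone, else gray."""
    if ccar_pct <= do_zone_upper:
        return CcarZone.DO_ZONE
    if ccar_pct >= non_do_zone_lower:
        return CcarZone.NON_DO_ZONE
    return CcarZone.GRAY_ZONE


def predict_do(ccar_pct: float, cutoff: float = DO_CUTOFF_PCT) -> bool:
    """Binary DO prediction: positive iff CCAR strictly below the cut-off.

    Lower CCAR (less CSF reserve) means higher DO risk.  The boundary value
    itself classifies as non-DO.
    """
    return ccar_pct < cutoff


def outcome_zone(
    ccar_pct: float,
    poor_upper: float = DO_ZONE_UPPER_PCT,
    good_lower: float = GOOD_OUTCOME_LOWER_PCT,
) -> OutcomeZone:
    """Outcome zones: <=14.3 poor/fair recovery, >=45.2 good/excellent, else indeterminate."""
    if ccar_pct <= poor_upper:
        return OutcomeZone.POOR_OR_FAIR
    if ccar_pct >= good_lower:
        return OutcomeZone.GOOD_OR_EXCELLENT
    return OutcomeZone.INDETERMINATE


def score_panel(inputs: ScoreInputs, mjoa: MjoaPair | None = None) -> ScorePanel:
    """Compute the full score panel for one patient from averaged areas."""
    o = ocar(inputs.mass_area, inputs.canal_area)
    s = scar(inputs.cord_area, inputs.dural_sac_ref_area)
    c = ccar(o, s)
    rr = recovery_rate(mjoa) if mjoa is not None else None
    return ScorePanel(
        ocar=o,
        scar=s,
        ccar=c,
        ccar_out_of_range=not (0.0 <= c <= 100.0),
        rr=rr,
        rr_grade=grade_rr(rr),
        ccar_zone=ccar_zone(c),
        outcome_zone=outcome_zone(c),
    )
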