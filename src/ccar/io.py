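"""Cohort table I/O, scoring columns, and phantom directory I/O.

Cohort CSV dialect: UTF-8, comma-separated, one header row, "." decimal,
units embedded in column names (``*_mm2``, ``*_pct``, ``*_yr``).  One row
per patient; the 20 raw area readings (5 sites x 2 observers x 2 repeats)
are wide columns named ``<site>_<observer>_r<repeat>_mm2``.  The three
latent generator scores travel in optional ``*_true_pct`` columns so a
simulated cohort round-trips exactly; they are NaN for real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, scores
from .geometry import MEASUREMENT_SITES, AreaMeasurement, Calibration
from .scores import MjoaPair
from .synthetic import OBSERVERS, SATO_TYPES, SEGMENTS, PatientRecord, PhantomSlice

__all__ = [
    "SchemaError",
    "IntegrityError",
    "CohortTable",
    "AREA_COLUMNS",
    "REQUIRED_COLUMNS",
    "records_to_frame",
    "load_cohort",
    "write_cohort",
    "score_cohort",
    "observer_score_matrix",
    "write_phantom_dir",
    "read_phantom_dir",
]


class SchemaError(ValueError):
    """The file does not conform to the cohort CSV schema."""


class IntegrityError(ValueError):
    """The file parses but violates a data-integrity constraint."""


AREA_COLUMNS = tuple(
    f"{site}_{obs}_r{rep}_mm2"
    for site in MEASUREMENT_SITES
    for obs in OBSERVERS
    for rep in (1, 2)
)
TRUE_COLUMNS = ("ocar_true_pct", "scar_true_pct", "ccar_true_pct")
REQUIRED_COLUMNS = (
    "id",
    "sex",
    "age_yr",
    "followup_yr",
    "do_status",
    "segment",
    "sato_type",
    "tts",
    "cs",
    "bs",
    "mjoa_pre",
    "mjoa_followup",
    *AREA_COLUMNS,
)


@dataclass(frozen=True)
class CohortTable:
    """Validated cohort: accepted records plus row-level diagnostics."""

    records: tuple[PatientRecord, ...]
    diagnostics: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "sex": r.sex,
            "age_yr": r.age,
            "followup_yr": r.followup_yr,
            "do_status": r.do_status,
            "segment": r.segment,
            "sato_type": r.sato_type,
            "tts": r.tts,
            "cs": r.cs,
            "bs": r.bs,
            "mjoa_pre": r.mjoa.pre,
            "mjoa_followup": r.mjoa.followup,
        }
        for m in r.measurements:
            row[f"{m.site}_{m.observer}_r{m.repeat}_mm2"] = m.value
        row["ocar_true_pct"] = r.true_ocar
        row["scar_true_pct"] = r.true_scar
        row["ccar_true_pct"] = r.true_ccar
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(TRUE_COLUMNS))


def write_cohort(records, path: str | Path) -> None:
    """Write patient records to the cohort CSV."""
    records_to_frame(records).to_csv(Path(path), index=False)


def _row_to_record(row: pd.Series) -> PatientRecord:
    if row["sex"] not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {row['sex']!r}")
    if row["segment"] not in SEGMENTS:
        raise ValueError(f"segment must be one of {SEGMENTS}, got {row['segment']!r}")
    if row["sato_type"] not in SATO_TYPES:
        raise ValueError(f"sato_type must be one of {SATO_TYPES}, got {row['sato_type']!r}")
    mjoa = MjoaPair(pre=int(row["mjoa_pre"]), followup=int(row["mjoa_followup"]))
    for col in ("mjoa_pre", "mjoa_followup"):
        if float(row[col]) != int(row[col]):
            raise ValueError(f"{col} must be an integer, got {row[col]}")
    measurements = []
    for site in MEASUREMENT_SITES:
        for obs in OBSERVERS:
            for rep in (1, 2):
                value = float(row[f"{site}_{obs}_r{rep}_mm2"])
                if not math.isfinite(value):
                    raise ValueError(f"non-finite area in {site}_{obs}_r{rep}_mm2")
                measurements.append(
                    AreaMeasurement(value=value, site=site, observer=obs, repeat=rep)
                )
    age = float(row["age_yr"])
    if not (0 < age < 130):
        raise ValueError(f"implausible age {age}")
    followup_yr = float(row["followup_yr"])
    if followup_yr < 0:
        raise ValueError(f"negative follow-up time {followup_yr}")
    return PatientRecord(
        id=str(row["id"]),
        sex=str(row["sex"]),
        age=age,
        followup_yr=followup_yr,
        do_status=_parse_bool(row["do_status"]),
        segment=str(row["segment"]),
        sato_type=str(row["sato_type"]),
        tts=_parse_bool(row["tts"]),
        cs=_parse_bool(row["cs"]),
        bs=_parse_bool(row["bs"]),
        mjoa=mjoa,
        measurements=tuple(measurements),
        true_ocar=float(row.get("ocar_true_pct", float("nan"))),
        true_scar=float(row.get("scar_true_pct", float("nan"))),
        true_ccar=float(row.get("ccar_true_pct", float("nan"))),
    )


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def load_cohort(path: str | Path, strict: bool = False) -> CohortTable:
    """Load and validate a cohort CSV.

    Missing required columns or an empty file raise :class:`SchemaError`;
    duplicate ids raise :class:`IntegrityError`.  Rows that fail validation
    (e.g. an mJOA score outside 0..11) are rejected with a row-level
    diagnostic; with ``strict=True`` any rejected row raises instead.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a parseable cohort CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    dupes = frame["id"][frame["id"].duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"{path}: duplicate ids {dupes}")

    records: list[PatientRecord] = []
    diagnostics: list[str] = []
    for idx, row in frame.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValueError, KeyError) as exc:
            msg = f"row {idx} (id={row.get('id', '?')}): {exc}"
            if strict:
                raise IntegrityError(msg) from exc
            diagnostics.append(msg)
    return CohortTable(records=tuple(records), diagnostics=tuple(diagnostics))


# -- scoring ------------------------------------------------------------------


def _averaged_areas(record: PatientRecord) -> dict[str, float]:
    by_site: dict[str, list[AreaMeasurement]] = {s: [] for s in MEASUREMENT_SITES}
    for m in record.measurements:
        by_site[m.site].append(m)
    return {site: geometry.average_repeats(ms) for site, ms in by_site.items()}


def score_record(record: PatientRecord) -> scores.ScorePanel:
    """Score one patient from the observer-averaged areas."""
    avg = _averaged_areas(record)
    inputs = scores.ScoreInputs(
        canal_area=avg["canal_ct"],
        mass_area=avg["mass_ct"],
        dural_sac_ref_area=geometry.reference_dural_sac_area(
            avg["dural_sac_upper_mri"], avg["dural_sac_lower_mri"]
        ),
        cord_area=avg["cord_mri"],
    )
    return scores.score_panel(inputs, record.mjoa)


def score_cohort(table: CohortTable | list[PatientRecord]) -> pd.DataFrame:
    """Cohort frame with the score columns appended.

    Appends ocar_pct, scar_pct, ccar_pct, ccar_out_of_range, rr_pct,
    rr_grade, ccar_zone, outcome_zone.
    """
    records = table.records if isinstance(table, CohortTable) else tuple(table)
    frame = records_to_frame(records)
    panels = [score_record(r) for r in records]
    frame["ocar_pct"] = [p.ocar for p in panels]
    frame["scar_pct"] = [p.scar for p in panels]
    frame["ccar_pct"] = [p.ccar for p in panels]
    frame["ccar_out_of_range"] = [p.ccar_out_of_range for p in panels]
    frame["rr_pct"] = [p.rr if p.rr is not None else np.nan for p in panels]
    frame["rr_grade"] = [p.rr_grade.value if p.rr_grade is not None else "" for p in panels]
    frame["ccar_zone"] = [p.ccar_zone.value for p in panels]
    frame["outcome_zone"] = [p.outcome_zone.value for p in panels]
    return frame


def observer_score_matrix(records) -> np.ndarray:
    """Subjects x observers matrix of CCAR, one column per observer.

    Each observer's CCAR uses the mean of that observer's two repeats at
    every site — the reliability analysis asks how well the two raters'
    end-to-end scores agree.
    """
    cols = []
    for obs in OBSERVERS:
        vals = []
        for r in records:
            avg = {
                site: geometry.average_repeats(
                    [m for m in r.measurements if m.site == site and m.observer == obs]
                )
                for site in MEASUREMENT_SITES
            }
            o = scores.ocar(avg["mass_ct"], avg["canal_ct"])
            s = scores.scar(
                avg["cord_mri"],
                geometry.reference_dural_sac_area(
                    avg["dural_sac_upper_mri"], avg["dural_sac_lower_mri"]
                ),
            )
            vals.append(scores.ccar(o, s))
        cols.append(vals)
    return np.asarray(cols, dtype=float).T


# -- phantom directory I/O ----------------------------------------------------


def write_phantom_dir(slice_: PhantomSlice, directory: str | Path, name: str = "phantom") -> None:
    """Write each mask as ``<name>_<structure>.png`` plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for structure, mask in slice_.masks.items():
        geometry.write_mask_png(mask, directory / f"{name}_{structure}.png")
    geometry.write_sidecar(
        directory / f"{name}.json", slice_.calibration, slice_.truth_mm2
    )


def read_phantom_dir(directory: str | Path, name: str = "phantom") -> PhantomSlice:
    directory = Path(directory)
    calibration, truth = geometry.read_sidecar(directory / f"{name}.json")
    masks = {
        structure: geometry.read_mask_png(directory / f"{name}_{structure}.png")
        for structure in truth
    }
    return PhantomSlice(masks=masks, calibration=calibration, truth_mm2=truth)
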