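"""Cohort construction from raw encounter and serum-creatinine tables.

Turns longitudinal serum creatinine (SCr) measurements into an analysis
cohort: a baseline SCr per stay, KDIGO stage-1 (creatinine-only) AKI labels
with onset times, eligibility filtering of patients with reduced kidney
function at admission, and the estimation point from which model features
may be drawn.

Time is real-valued hours relative to admission (admission = 0); all
windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# KDIGO stage-1 serum-creatinine criteria
KDIGO_ABS_RISE_MGDL = 0.3
KDIGO_ABS_WINDOW_H = 48.0
KDIGO_RATIO = 1.5

PRE_ADMISSION_WINDOW_H = 48.0   # baseline lookback: 2 days before admission
ADMISSION_SCR_WINDOW_H = 24.0   # eligibility screen on early in-stay SCr
ADMISSION_SCR_MAX_MGDL = 1.3
EGFR_MIN = 60.0                 # mL/min/1.73 m^2
ESTIMATION_LEAD_H = 24.0        # features taken 1 day before onset / last SCr

ENCOUNTER_COLUMNS = ["encounter_id", "age", "sex", "race", "admission_ts"]
SCR_COLUMNS = ["encounter_id", "t_hours", "scr_mgdl"]


class MissingColumnError(KeyError):
    """A required column is absent from an input table."""

    def __init__(self, column: str, table: str):
        super().__init__(column)
        self.column = column
        self.table = table

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"missing required column {self.column!r} in {self.table}"


@dataclass(frozen=True)
class CreatinineSeries:
    """All SCr measurements for one encounter, sorted by time.

    Times are hours relative to admission (may be negative for
    pre-admission draws); values are mg/dL and must be positive.
    """

    encounter_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0:
            raise ValueError("creatinine series must contain at least one point")
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if np.any(v <= 0):
            raise ValueError("serum creatinine must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BaselineScr:
    value: float
    source: str  # "pre-admission" | "first-post-admission"
    t: float     # measurement time of the baseline draw, hours

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("baseline creatinine must be positive")


@dataclass
class EncounterRecord:
    """One inpatient stay: demographics, SCr series, features, outcome."""

    encounter_id: str
    age: float
    sex: str
    race: str
    scr_series: Optional[CreatinineSeries] = None
    features: Optional[pd.Series] = None
    subgroup_id: Optional[str] = None
    label: Optional[str] = None       # "AKI" | "no-AKI"
    onset_t: Optional[float] = None   # hours, present iff label == "AKI"
    baseline: Optional[BaselineScr] = None
    estimation_t: Optional[float] = None


def compute_baseline_scr(series: CreatinineSeries) -> BaselineScr:
    """Baseline SCr: the last measurement within 2 days before admission,
    else the first measurement after admission."""
    t, v = series.times, series.values
    pre = (t >= -PRE_ADMISSION_WINDOW_H) & (t < 0)
    if pre.any():
        i = np.flatnonzero(pre)[-1]
        return BaselineScr(float(v[i]), "pre-admission", float(t[i]))
    post = t >= 0
    if post.any():
        i = np.flatnonzero(post)[0]
        return BaselineScr(float(v[i]), "first-post-admission", float(t[i]))
    raise ValueError("no baseline available")


def label_aki_kdigo(
    series: CreatinineSeries, baseline: BaselineScr
) -> tuple[str, Optional[float]]:
    """Rolling KDIGO stage-1 SCr assessment.

    Each in-stay measurement at time t is AKI-positive if either
    (a) it exceeds the minimum SCr in its trailing 48 h window (baseline
    included when the baseline draw falls in the window) by >= 0.3 mg/dL, or
    (b) it reaches 1.5x the fixed admission baseline.
    Returns ("AKI", earliest positive time) or ("no-AKI", None).
    """
    t, v = series.times, series.values
    for i in range(len(t)):
        if t[i] < 0:
            continue  # only in-stay measures are assessed
        lo = t[i] - KDIGO_ABS_WINDOW_H
        window = v[(t >= lo) & (t <= t[i])]
        ref = window.min()
        if lo <= baseline.t <= t[i]:
            ref = min(ref, baseline.value)
        # tiny tolerance so exact-threshold values (e.g. 1.5x of 0.8) trigger
        if (
            v[i] - ref >= KDIGO_ABS_RISE_MGDL - 1e-9
            or v[i] >= KDIGO_RATIO * baseline.value - 1e-9
        ):
            return "AKI", float(t[i])
    return "no-AKI", None


_BLACK_RACE = {"african american", "black"}


def mdrd_egfr(scr: float, age: float, sex: str, race: str) -> float:
    """4-variable IDMS-traceable MDRD estimated GFR, mL/min/1.73 m^2.

    175 * SCr^-1.154 * age^-0.203 * 0.742 (if female) * 1.212 (if Black).
    """
    if scr <= 0 or age <= 0:
        raise ValueError("scr and age must be positive")
    if age < 18:
        raise ValueError("MDRD is defined for adults (age >= 18)")
    egfr = 175.0 * scr ** -1.154 * age ** -0.203
    if sex.lower() == "female":
        egfr *= 0.742
    if race.lower() in _BLACK_RACE:
        egfr *= 1.212
    return egfr


EXCLUSION_REASONS = (
    "fewer than 2 SCr",
    "no baseline available",
    "eGFR < 60 at admission",
    "SCr > 1.3 within 24 h",
    "observation window too short",
)


def _first_exclusion_reason(rec: EncounterRecord) -> Optional[str]:
    s = rec.scr_series
    if s is None or len(s) < 2:
        return "fewer than 2 SCr"
    try:
        baseline = compute_baseline_scr(s)
    except ValueError:
        return "no baseline available"
    if mdrd_egfr(baseline.value, rec.age, rec.sex, rec.race) < EGFR_MIN:
        return "eGFR < 60 at admission"
    early = s.values[(s.times >= 0) & (s.times <= ADMISSION_SCR_WINDOW_H)]
    if early.size and early.max() > ADMISSION_SCR_MAX_MGDL:
        return "SCr > 1.3 within 24 h"
    rec.baseline = baseline
    return None


def apply_eligibility_filters(
    cohort: Sequence[EncounterRecord],
) -> tuple[list[EncounterRecord], dict[str, int]]:
    """Apply the exclusion cascade; a record failing several criteria is
    counted once, under the first matching reason."""
    tally = {reason: 0 for reason in EXCLUSION_REASONS[:4]}
    kept: list[EncounterRecord] = []
    for rec in cohort:
        reason = _first_exclusion_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            tally[reason] += 1
    return kept, tally


def set_estimation_point(record: EncounterRecord) -> float:
    """Estimation point: 24 h before AKI onset, or 24 h before the last
    SCr measurement for non-AKI stays."""
    if record.label is None:
        raise ValueError("record must be labeled before setting the estimation point")
    if record.label == "AKI":
        if record.onset_t is None:
            raise ValueError("AKI record lacks an onset time")
        est = record.onset_t - ESTIMATION_LEAD_H
    else:
        est = float(record.scr_series.times.max()) - ESTIMATION_LEAD_H
    if est < 0:
        raise ValueError("observation window too short")
    record.estimation_t = est
    return est


def _require_columns(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise MissingColumnError(col, table)


def read_encounters(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ENCOUNTER_COLUMNS, "encounters table")
    return df


def read_scr(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SCR_COLUMNS, "creatinine table")
    return df


def label_cohort(
    encounters: pd.DataFrame, scr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full labeling pipeline over tabular inputs.

    Returns (labels, exclusions): one row per kept encounter with label,
    onset, baseline and estimation point; and one row per excluded
    encounter with its (first) exclusion reason.
    """
    _require_columns(encounters, ENCOUNTER_COLUMNS[:4], "encounters table")
    _require_columns(scr, SCR_COLUMNS, "creatinine table")
    grouped = {eid: g for eid, g in scr.groupby("encounter_id")}
    records = []
    for row in encounters.itertuples(index=False):
        g = grouped.get(row.encounter_id)
        series = None
        if g is not None and len(g):
            series = CreatinineSeries(
                row.encounter_id,
                g["t_hours"].to_numpy(float),
                g["scr_mgdl"].to_numpy(float),
            )
        records.append(
            EncounterRecord(
                encounter_id=row.encounter_id,
                age=float(row.age),
                sex=str(row.sex),
                race=str(row.race),
                scr_series=series,
            )
        )
    kept, tally = apply_eligibility_filters(records)

    label_rows, excl_rows = [], []
    for rec in kept:
        label, onset = label_aki_kdigo(rec.scr_series, rec.baseline)
        rec.label, rec.onset_t = label, onset
        try:
            set_estimation_point(rec)
        except ValueError:
            excl_rows.append((rec.encounter_id, "observation window too short"))
            continue
        label_rows.append(
            (
                rec.encounter_id,
                rec.label,
                rec.onset_t if rec.onset_t is not None else np.nan,
                rec.baseline.value,
                rec.estimation_t,
            )
        )
    kept_ids = {r.encounter_id for r in kept}
    for rec in records:
        if rec.encounter_id not in kept_ids:
            excl_rows.append((rec.encounter_id, _first_exclusion_reason(rec)))

    labels = pd.DataFrame(
        label_rows,
        columns=["encounter_id", "label", "onset_t", "baseline_scr", "estimation_t"],
    )
    exclusions = pd.DataFrame(excl_rows, columns=["encounter_id", "reason"])
    return labels, exclusions


def cohort_proportions(counts: dict[str, int], total: int) -> dict[str, float]:
    """Percentages (one decimal, as conventionally printed) of named counts
    within a cohort total, e.g. event prevalence or sex split."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * c / total, 1) for k, c in counts.items()}
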