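"""Ingestion and eligibility filtering of longitudinal CBC tables.

Reads real or synthetic cohorts (tidy CSV, one row per blood draw), aligns
times to the first CDK4/6-inhibitor dose (day 0, pre-treatment negative),
derives the continuous-treatment episode from dispensing records, and applies
the cohort eligibility rules: at least five CBCs in the analysis window,
baseline MCV <= 98 fL (higher baseline values can indicate concurrent
conditions affecting RBC homeostasis), records restricted to
[-28 days, end of continuous treatment].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .synthetic_cohort import RECORD_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "PatientTimeline",
    "EligibilityRules",
    "read_cbc_table",
    "continuous_duration",
    "apply_eligibility",
]

#: Default dispensing cycle length (days): one dispensing covers the forward
#: interval of a standard 28-day CDK4/6i cycle.
CYCLE_DAYS = 28.0


@dataclass
class PatientTimeline:
    """All data for one patient, times in days relative to the first dose."""

    patient_id: str
    records: pd.DataFrame                       # RECORD_COLUMNS, sorted by t_days
    dispensing_days: np.ndarray | None = None   # ordered dispensing day offsets

    def __post_init__(self) -> None:
        self.records = self.records.sort_values("t_days").reset_index(drop=True)
        if self.dispensing_days is not None:
            self.dispensing_days = np.sort(np.asarray(self.dispensing_days, dtype=float))


@dataclass(frozen=True)
class EligibilityRules:
    """Cohort inclusion thresholds."""

    min_cbc: int = 5
    baseline_mcv_max: float = 98.0   # fL; strictly greater is excluded
    baseline_window: float = 28.0    # days before first dose
    gap_threshold: float = 30.0      # days; dispensing gap breaking continuity
    late_baseline_limit: float = 14.0  # fallback: earliest on-drug draw usable as baseline


def _schema_error(missing: list[str]) -> None:
    raise ValueError(f"input table is missing required column(s): {', '.join(missing)}")


def read_cbc_table(path, schema_config=None, dispensing_path=None) -> list[PatientTimeline]:
    """Read a tidy CBC CSV into per-patient timelines.

    Expected columns: ``patient_id``, either ``t_days`` or ``date`` +
    ``first_dose_date`` (ISO dates, converted to day offsets), and
    ``rbc_1e12_per_L``, ``mcv_fL``, ``mchc_g_dL``.  ``schema_config`` may be
    a dict or a YAML file path mapping actual column names to the expected
    ones (``{"MCV": "mcv_fL", ...}``).  ``dispensing_path`` optionally points
    to a CSV with ``patient_id`` and ``t_days`` or ``date`` rows, one per
    dispensing.  Duplicate (patient, t) rows keep the first occurrence.
    """
    df = _read_csv(path)
    if schema_config is not None:
        if isinstance(schema_config, (str, bytes)) or hasattr(schema_config, "read_text"):
            with open(schema_config) as fh:
                schema_config = yaml.safe_load(fh)
        df = df.rename(columns=schema_config)
    df = _to_day_offsets(df)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        _schema_error(missing)
    for col in ("t_days", "rbc_1e12_per_L", "mcv_fL", "mchc_g_dL"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"unparseable value(s) in column {col!r} at line(s) {rows}") from exc

    n_before = len(df)
    df = df.drop_duplicates(subset=["patient_id", "t_days"], keep="first")
    if len(df) < n_before:
        log.info("dropped %d duplicate (patient_id, t_days) rows", n_before - len(df))

    dispensing = None
    if dispensing_path is not None:
        dd = _to_day_offsets(_read_csv(dispensing_path))
        if "t_days" not in dd.columns:
            _schema_error(["t_days (or date + first_dose_date)"])
        dispensing = {pid: g["t_days"].to_numpy(float) for pid, g in dd.groupby("patient_id")}

    timelines = []
    for pid, grp in df.groupby("patient_id", sort=True):
        disp = dispensing.get(str(pid)) if dispensing else None
        timelines.append(PatientTimeline(str(pid), grp[RECORD_COLUMNS].copy(), disp))
    return timelines


def _read_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.read_csv(io.StringIO(fh.read()), comment="#")


def _to_day_offsets(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a calendar-date column to day offsets from the first dose."""
    if "t_days" in df.columns or "date" not in df.columns:
        return df
    if "first_dose_date" not in df.columns:
        _schema_error(["t_days (or date + first_dose_date)"])
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
        anchor = pd.to_datetime(df["first_dose_date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date value: {exc}") from exc
    df = df.copy()
    df["t_days"] = (dates - anchor).dt.days.astype(float)
    return df


def continuous_duration(timeline: PatientTimeline, gap_threshold: float = 30.0) -> float:
    """Length (days) of the first continuous treatment episode.

    Treatment is considered continuous while no inter-dispensing gap reaches
    ``gap_threshold`` days; the episode ends one 28-day cycle after its last
    dispensing (a dispensing covers a forward interval).  Without dispensing
    information the last record time is used and the assumption is logged.
    """
    disp = timeline.dispensing_days
    if disp is None or len(disp) == 0:
        log.info("patient %s has no dispensing info; using last CBC time as episode end",
                 timeline.patient_id)
        return float(timeline.records["t_days"].max())
    end = disp[0]
    for prev, nxt in zip(disp[:-1], disp[1:]):
        if nxt - prev >= gap_threshold:
            return float(prev + CYCLE_DAYS)
        end = nxt
    return float(end + CYCLE_DAYS)


def _baseline_mcv(records: pd.DataFrame, rules: EligibilityRules) -> float | None:
    """Baseline MCV: most recent draw at t <= 0 within the window; fallback to
    the earliest on-treatment draw within ``late_baseline_limit`` days."""
    pre = records[(records["t_days"] <= 0) & (records["t_days"] >= -rules.baseline_window)]
    if len(pre):
        return float(pre.loc[pre["t_days"].idxmax(), "mcv_fL"])
    early = records[(records["t_days"] > 0) & (records["t_days"] <= rules.late_baseline_limit)]
    if len(early):
        return float(early.loc[early["t_days"].idxmin(), "mcv_fL"])
    return None


def apply_eligibility(timelines: list[PatientTimeline],
                      rules: EligibilityRules = EligibilityRules(),
                      ) -> tuple[list[PatientTimeline], pd.DataFrame]:
    """Apply the cohort rules; return included timelines and an exclusion log.

    Per patient: records are trimmed to [-baseline_window, end of continuous
    treatment]; exclusion reasons (one primary reason each, first match
    wins): ``no_baseline``, ``insufficient_cbc_count`` (< min_cbc in-window
    draws), ``baseline_macrocytosis`` (baseline MCV strictly > 98 fL).
    Idempotent: re-running on the included set changes nothing.
    """
    included: list[PatientTimeline] = []
    reasons: list[dict] = []
    for tl in timelines:
        end = continuous_duration(tl, rules.gap_threshold)
        recs = tl.records[(tl.records["t_days"] >= -rules.baseline_window)
                          & (tl.records["t_days"] <= end)].reset_index(drop=True)
        baseline = _baseline_mcv(recs, rules) if len(recs) else None
        if baseline is None:
            reasons.append({"patient_id": tl.patient_id, "reason": "no_baseline"})
            continue
        if len(recs) < rules.min_cbc:
            reasons.append({"patient_id": tl.patient_id, "reason": "insufficient_cbc_count"})
            continue
        if baseline > rules.baseline_mcv_max:
            reasons.append({"patient_id": tl.patient_id, "reason": "baseline_macrocytosis"})
            continue
        included.append(PatientTimeline(tl.patient_id, recs, tl.dispensing_days))
    exclusion_log = pd.DataFrame(reasons, columns=["patient_id", "reason"])
    return included, exclusion_log
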