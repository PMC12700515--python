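"""Collapse window/day features into the 20 monthly digital phenotypes.

A follow-up month is a 30-day block from enrollment (uniform block length
keeps the wake/sleep window-count thresholds comparable across months).
Months with fewer than 720 wake or fewer than 480 sleep 5-minute windows
are excluded from modelling.  Eight window features ({accelerometer energy,
gyroscope energy, NN count, RMSSD} x {wake, sleep}) each contribute a
monthly mean and a monthly sample SD; the sleep:wake ratio and steps per
minute contribute means and SDs across valid (>= 18 h recorded) days —
20 phenotypes in all.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError
from .features import MIN_HOURS_PER_DAY, summarize_days
from .simulate import PHENOTYPE_COLUMNS, PANSS_DIMENSIONS, DAYS_PER_MONTH

MIN_WAKE_WINDOWS = 720
MIN_SLEEP_WINDOWS = 480

WINDOW_FEATURES = ("acc_ste", "gyro_ste", "nn_count", "rmssd")


def month_index_from_timestamps(window_start: pd.Series, enrollment: pd.Series) -> pd.Series:
    """1-based 30-day-block index of each window relative to enrollment."""
    delta = pd.to_datetime(window_start) - pd.to_datetime(enrollment)
    return (delta.dt.total_seconds() // (DAYS_PER_MONTH * 86400)).astype(int) + 1


def aggregate_month(
    windows: pd.DataFrame,
    days: pd.DataFrame | None,
    patient_id: str,
    month_index: int,
    min_wake: int = MIN_WAKE_WINDOWS,
    min_sleep: int = MIN_SLEEP_WINDOWS,
    sd_scope: str = "windows",
) -> dict:
    """Phenotype part of one patient-month row.

    ``windows`` holds that patient-month's feature windows; ``days`` the
    patient's daily summaries restricted to the month (only valid days feed
    the ratio/steps phenotypes).  Missing RMSSD windows are omitted from the
    RMSSD aggregates only.  ``sd_scope`` picks whether monthly SDs of window
    features are taken across windows (default) or across daily means.
    """
    if sd_scope not in ("windows", "days"):
        raise DataError(f"sd_scope must be 'windows' or 'days', got {sd_scope!r}")
    row: dict = {"patient_id": patient_id, "month_index": int(month_index)}
    n_wake = int((windows["state"] == "wake").sum()) if len(windows) else 0
    n_sleep = int((windows["state"] == "sleep").sum()) if len(windows) else 0
    row["n_wake_windows"] = n_wake
    row["n_sleep_windows"] = n_sleep
    row["included"] = bool(n_wake >= min_wake and n_sleep >= min_sleep)

    for feat in WINDOW_FEATURES:
        for state in ("wake", "sleep"):
            if len(windows):
                vals = windows.loc[windows["state"] == state, feat].dropna()
            else:
                vals = pd.Series(dtype=float)
            if sd_scope == "days" and len(vals):
                sub = windows.loc[windows["state"] == state, ["window_start", feat]].dropna()
                daily = sub.groupby(pd.to_datetime(sub["window_start"]).dt.date)[feat].mean()
                row[f"{feat}_{state}_mean"] = float(daily.mean()) if len(daily) else np.nan
                row[f"{feat}_{state}_sd"] = float(daily.std(ddof=1)) if len(daily) > 1 else np.nan
            else:
                row[f"{feat}_{state}_mean"] = float(vals.mean()) if len(vals) else np.nan
                row[f"{feat}_{state}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan

    if days is not None and len(days):
        valid = days[days["valid"]]
    else:
        valid = pd.DataFrame(columns=["sleep_wake_ratio", "steps_per_minute"])
    row["n_valid_days"] = int(len(valid))
    for col, name in (("sleep_wake_ratio", "sleep_wake_ratio"), ("steps_per_minute", "steps_per_minute")):
        vals = valid[col].dropna() if len(valid) else pd.Series(dtype=float)
        row[f"{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
        row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return row


def aggregate_months(
    windows: pd.DataFrame,
    enrollment: Mapping[str, pd.Timestamp] | None = None,
    min_wake: int = MIN_WAKE_WINDOWS,
    min_sleep: int = MIN_SLEEP_WINDOWS,
    min_hours: float = MIN_HOURS_PER_DAY,
    sd_scope: str = "windows",
) -> pd.DataFrame:
    """All patient-month phenotype rows for a feature-window table.

    Enrollment dates anchor the 30-day blocks; when absent, each patient's
    first recorded window day is used.  Output is one row per observed
    (patient, month), sorted, with the inclusion flag set by the wake/sleep
    window-count thresholds.
    """
    if not len(windows):
        return pd.DataFrame(columns=["patient_id", "month_index", *PHENOTYPE_COLUMNS, "included"])
    df = windows.copy()
    df["window_start"] = pd.to_datetime(df["window_start"])
    if enrollment is None:
        enrollment = df.groupby("patient_id")["window_start"].min().dt.normalize().to_dict()
    enr = df["patient_id"].map(lambda p: pd.to_datetime(enrollment[p]))
    df["month_index"] = month_index_from_timestamps(df["window_start"], enr)

    day_table = summarize_days(df, min_hours=min_hours)
    day_table["month_index"] = month_index_from_timestamps(
        pd.to_datetime(day_table["date"]), day_table["patient_id"].map(lambda p: pd.to_datetime(enrollment[p]))
    )

    rows = []
    for (pid, m), sub in df.groupby(["patient_id", "month_index"], sort=True):
        dsub = day_table[(day_table["patient_id"] == pid) & (day_table["month_index"] == m)]
        rows.append(
            aggregate_month(sub, dsub, pid, m, min_wake=min_wake, min_sleep=min_sleep, sd_scope=sd_scope)
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["patient_id", "month_index"]).reset_index(drop=True)


def build_analysis_table(
    patient_months: pd.DataFrame,
    clinical: pd.DataFrame,
    alignment: str = "preceding",
) -> pd.DataFrame:
    """Join monthly phenotypes with the clinical table into the modelling set.

    Keeps only included sensor months that have a PANSS record.  Visits are
    timestamped at the end of each follow-up block, so ``preceding``
    (default) joins a rating to the block that ends at the visit (equal
    month indices); ``same`` joins it to the block that begins at the visit.
    Clinical rows without a matching included sensor month are dropped.
    """
    if alignment not in ("preceding", "same"):
        raise DataError(f"alignment must be 'preceding' or 'same', got {alignment!r}")
    for name, tab in (("sensor", patient_months), ("clinical", clinical)):
        dup = tab.duplicated(subset=["patient_id", "month_index"])
        if dup.any():
            offenders = tab.loc[dup, ["patient_id", "month_index"]].values.tolist()
            raise DataError(f"duplicate (patient, month) keys in {name} table: {offenders}")
    sensor = patient_months[patient_months["included"]].copy()
    if alignment == "same":
        sensor = sensor.copy()
        sensor["month_index"] = sensor["month_index"] - 1
        sensor = sensor[sensor["month_index"] >= 1]
    clin = clinical.drop(columns=["enrollment_date"], errors="ignore")
    merged = clin.merge(sensor, on=["patient_id", "month_index"], how="inner")
    front = ["patient_id", "month_index", *PHENOTYPE_COLUMNS, *PANSS_DIMENSIONS]
    rest = [c for c in merged.columns if c not in front]
    return merged[[c for c in front if c in merged.columns] + rest]


def analysis_table_schema() -> dict:
    """Column dictionary for ``analysis_table.csv``."""
    schema = {
        "patient_id": "patient identifier",
        "month_index": "1-based 30-day follow-up block, visits at block end",
    }
    for col in PHENOTYPE_COLUMNS:
        feat, rest = col.rsplit("_", 1)
        schema[col] = f"monthly {rest} of {feat.replace('_', ' ')}"
    for dim in PANSS_DIMENSIONS:
        schema[dim] = f"PANSS {dim.replace('_', '/')} dimension score"
    schema.update(
        {
            "gender": "0 = male, 1 = female",
            "diagnosis_group": "diagnostic subgroup indicator",
            "chlorpromazine_equivalents": "antipsychotic dose, mg/day CPZ equivalents",
            "fluoxetine_equivalents": "antidepressant dose, mg/day fluoxetine equivalents",
            "followup_month": "months since enrollment (continuous time covariate)",
            "included": "wake windows >= 720 and sleep windows >= 480",
            "n_wake_windows": "count of recorded wake windows in the block",
            "n_sleep_windows": "count of recorded sleep windows in the block",
            "n_valid_days": "days with >= 18 h recorded in the block",
        }
    )
    return schema


def write_analysis_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
    with open(str(path).replace(".csv", ".schema.json"), "w") as fh:
        json.dump(analysis_table_schema(), fh, indent=2)
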