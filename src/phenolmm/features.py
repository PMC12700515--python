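"""Per-window and per-day digital-phenotype features from raw smartwatch streams.

The atomic unit is a 5-minute window of sensor data.  From the inertial
sensors we compute the short-time energy (STE) of the Euclidean norm of the
3-axis signal — the sum of squared norm samples, an activity-count-like
motility measure.  From photoplethysmography interpulse intervals (IPIs),
after artifact removal, we compute the normal-to-normal (NN) interval count
(a sympathovagal-balance proxy) and the RMSSD of successive differences (a
parasympathetic-activity proxy).  Daily summaries carry the sleep:wake ratio
and steps per minute, valid only on days with >= 18 h of recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Default absolute physiological band for NN intervals, in ms.
IPI_BAND_MS: tuple[float, float] = (300.0, 2000.0)
#: Default relative tolerance around the running median of retained intervals.
IPI_TOLERANCE: float = 0.20
#: Number of previous retained intervals entering the running median.
IPI_MEDIAN_WINDOW: int = 10
#: Minimum recorded hours for a day to enter the daily phenotypes.
MIN_HOURS_PER_DAY: float = 18.0

WINDOW_MINUTES = 5
WINDOWS_PER_DAY = 24 * 60 // WINDOW_MINUTES  # 288


@dataclass(frozen=True)
class DaySummary:
    """One patient-day of recording-coverage and daily phenotypes."""

    patient_id: str
    date: object
    hours_recorded: float
    sleep_wake_ratio: float  # NaN when no wake hours
    steps_per_minute: float
    valid: bool


def euclidean_norm(x: Sequence[float], y: Sequence[float], z: Sequence[float]) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of a 3-axis stream."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise DataError(
            f"axis streams differ in length: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def compute_ste(norm_samples: Sequence[float]) -> float:
    """Short-time energy of a window: the sum of squared norm samples.

    Empty windows yield NaN (a dropped window), never a spurious zero.
    Order-invariant and additive over any partition of the window.
    """
    arr = np.asarray(norm_samples, dtype=float)
    if arr.size == 0:
        return float("nan")
    if not np.all(np.isfinite(arr)):
        raise DataError("norm samples must be finite")
    return float(np.sum(arr * arr))


def clean_interpulse(
    ipi_ms: Sequence[float],
    band_ms: tuple[float, float] = IPI_BAND_MS,
    tolerance: float = IPI_TOLERANCE,
    median_window: int = IPI_MEDIAN_WINDOW,
) -> np.ndarray:
    """Artifact-removal rule turning raw interpulse intervals into NN intervals.

    An interval is retained when it lies inside the absolute band
    ``band_ms`` AND within ``tolerance`` (relative) of the running median of
    the previous ``median_window`` retained intervals.  Until any interval
    has been retained the relative criterion is vacuous.  Order is
    preserved; the output is a subsequence of the input, so the rule is
    idempotent.
    """
    lo, hi = band_ms
    out: list[float] = []
    for v in np.asarray(ipi_ms, dtype=float):
        if not (lo <= v <= hi):
            continue
        if out:
            ref = float(np.median(out[-median_window:]))
            if abs(v - ref) > tolerance * ref:
                continue
        out.append(float(v))
    return np.asarray(out, dtype=float)


def window_heart_features(nn_ms: Sequence[float]) -> tuple[int, float]:
    """NN count and RMSSD for one 5-minute window of cleaned intervals.

    RMSSD is sqrt(mean(successive differences squared)); with fewer than two
    intervals it is undefined and returned as NaN.
    """
    arr = np.asarray(nn_ms, dtype=float)
    n = int(arr.size)
    if n < 2:
        return n, float("nan")
    d = np.diff(arr)
    return n, float(np.sqrt(np.mean(d * d)))


def extract_window_features(windows: pd.DataFrame, **clean_kwargs) -> pd.DataFrame:
    """Compute per-window features from a raw-stream window table.

    ``windows`` must carry object columns ``acc_norm``/``gyro_norm`` (norm
    sample arrays) or ``acc_x/acc_y/acc_z`` etc., plus ``ipi_ms`` (interval
    lists).  Returns the table with ``acc_ste, gyro_ste, nn_count, rmssd``
    columns, dropping the raw blobs.
    """
    df = windows.copy()
    for sensor in ("acc", "gyro"):
        if f"{sensor}_norm" in df.columns:
            norms = df[f"{sensor}_norm"]
        elif {f"{sensor}_x", f"{sensor}_y", f"{sensor}_z"} <= set(df.columns):
            norms = [
                euclidean_norm(x, y, z)
                for x, y, z in zip(df[f"{sensor}_x"], df[f"{sensor}_y"], df[f"{sensor}_z"])
            ]
        else:
            raise DataError(f"no {sensor} stream columns in window table")
        df[f"{sensor}_ste"] = [compute_ste(v) for v in norms]
    nn, rm = [], []
    for raw in df["ipi_ms"]:
        cleaned = clean_interpulse(raw, **clean_kwargs)
        c, r = window_heart_features(cleaned)
        nn.append(c)
        rm.append(r)
    df["nn_count"] = nn
    df["rmssd"] = rm
    drop = [c for c in df.columns if c.endswith(("_norm", "_x", "_y", "_z"))] + ["ipi_ms"]
    return df.drop(columns=[c for c in drop if c in df.columns])


def daily_summary(
    day_windows: pd.DataFrame,
    steps_per_minute_stream: Sequence[float] | None = None,
    min_hours: float = MIN_HOURS_PER_DAY,
) -> DaySummary:
    """Summarize one patient-day of 5-minute windows.

    Recorded hours count windows with any sensor payload (non-wear appears
    as absent windows).  The sleep:wake ratio is sleep hours over wake
    hours, NaN when no wake window was recorded.  Steps per minute divide
    total steps by recorded minutes.  A day is valid iff it has at least
    ``min_hours`` recorded.
    """
    pids = day_windows["patient_id"].unique()
    if len(pids) != 1:
        raise DataError(f"daily_summary expects one patient, got {list(pids)}")
    dates = pd.to_datetime(day_windows["window_start"]).dt.date.unique()
    if len(dates) != 1:
        raise DataError(f"daily_summary expects one calendar date, got {list(dates)}")
    n = len(day_windows)
    hours = n * WINDOW_MINUTES / 60.0
    n_sleep = int((day_windows["state"] == "sleep").sum())
    n_wake = n - n_sleep
    ratio = (n_sleep / n_wake) if n_wake > 0 else float("nan")
    if steps_per_minute_stream is not None:
        total_steps = float(np.sum(steps_per_minute_stream))
    else:
        total_steps = float(day_windows["steps"].sum())
    spm = total_steps / (n * WINDOW_MINUTES) if n else float("nan")
    return DaySummary(
        patient_id=str(pids[0]),
        date=dates[0],
        hours_recorded=hours,
        sleep_wake_ratio=ratio,
        steps_per_minute=spm,
        valid=hours >= min_hours,
    )


def summarize_days(windows: pd.DataFrame, min_hours: float = MIN_HOURS_PER_DAY) -> pd.DataFrame:
    """Vectorized daily summaries for a full window table.

    Equivalent to applying :func:`daily_summary` per (patient, date); kept
    vectorized because cohort-scale tables run to millions of windows.
    """
    df = windows[["patient_id", "window_start", "state", "steps"]].copy()
    df["date"] = pd.to_datetime(df["window_start"]).dt.date
    g = df.groupby(["patient_id", "date"], sort=True)
    out = g.agg(
        n_windows=("state", "size"),
        n_sleep=("state", lambda s: int((s == "sleep").sum())),
        steps=("steps", "sum"),
    ).reset_index()
    out["hours_recorded"] = out["n_windows"] * WINDOW_MINUTES / 60.0
    n_wake = out["n_windows"] - out["n_sleep"]
    out["sleep_wake_ratio"] = np.where(n_wake > 0, out["n_sleep"] / n_wake.replace(0, np.nan), np.nan)
    out["steps_per_minute"] = out["steps"] / (out["n_windows"] * WINDOW_MINUTES)
    out["valid"] = out["hours_recorded"] >= min_hours
    return out[
        ["patient_id", "date", "hours_recorded", "sleep_wake_ratio", "steps_per_minute", "valid"]
    ]
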