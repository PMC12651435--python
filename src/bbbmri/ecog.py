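"""Electrocorticography burden metrics.

Spreading-depolarisation (SD) and electrographic-seizure annotations are
reduced to daily totals and peak summary metrics: TDDD (total SD-induced
depression duration per day, minutes) with its peak PTDDD, the peak daily SD
count (peak_SD), and the seizure analogues TSDD / PTSDD / peak_seizure.

Day indexing: the first 24-hour period after the initial haemorrhage is day
0, the second day 1, and so on.  An event belongs wholly to its onset day;
no midnight splitting is applied.  Days are counted as recorded from an
explicit recording interval, so unmonitored days do not enter the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEIZURE_MIN_DURATION_MIN = 10.0 / 60.0   # definitional 10-second minimum


@dataclass
class EcogSummary:
    daily: pd.DataFrame          # index: day; columns: TDDD, SD_count, TSDD, seizure_count
    PTDDD: float
    peak_SD: int
    PTSDD: float
    peak_seizure: int
    recording_days: int


def assign_day(onset_hours: float | np.ndarray) -> np.ndarray | int:
    """Day index of an onset time in hours post-ictus: ``floor(hours / 24)``."""
    onset = np.asarray(onset_hours, dtype=float)
    if np.any(onset < 0):
        raise ValueError("onset times must be >= 0 hours post-ictus")
    days = np.floor(onset / 24.0).astype(int)
    return int(days) if np.isscalar(onset_hours) else days


def validate_events(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Enforce annotation-level duration rules.

    Seizures shorter than 10 s are rejected, as are events with negative
    durations or onsets and malformed rows; the report counts each reason.
    """
    report = {"n_input": len(events), "rejected": {}}
    required = {"kind", "onset_hours", "duration_min"}
    missing_cols = required - set(events.columns)
    if missing_cols:
        raise ValueError(f"event table lacks columns: {sorted(missing_cols)}")
    df = events.copy()
    numeric = df[["onset_hours", "duration_min"]].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1) | ~df["kind"].isin(["SD", "seizure"])
    df[["onset_hours", "duration_min"]] = numeric

    def _reject(mask: pd.Series, reason: str) -> None:
        n = int(mask.sum())
        if n:
            report["rejected"][reason] = n
        nonlocal keep
        keep &= ~mask

    keep = pd.Series(True, index=df.index)
    _reject(bad_rows, "malformed row")
    _reject(~bad_rows & (df["onset_hours"] < 0), "negative onset")
    _reject(~bad_rows & (df["duration_min"] < 0), "negative duration")
    _reject(~bad_rows & (df["kind"] == "seizure")
            & (df["duration_min"] < SEIZURE_MIN_DURATION_MIN),
            "seizure shorter than 10 s")
    out = df[keep].reset_index(drop=True)
    report["n_kept"] = len(out)
    return out, report


def daily_totals(events: pd.DataFrame, kind: str, recording_days: int) -> pd.DataFrame:
    """Per-day duration totals and event counts for one event kind.

    Recorded days without events contribute zeros; events beyond the
    recording interval are ignored.
    """
    if recording_days < 1:
        raise ValueError("need at least one recording day")
    sel = events[events["kind"] == kind]
    days = assign_day(sel["onset_hours"].to_numpy()) if len(sel) else np.array([], int)
    in_window = days < recording_days
    frame = pd.DataFrame({"day": days[in_window],
                          "duration_min": sel["duration_min"].to_numpy()[in_window]})
    grouped = frame.groupby("day").agg(total_min=("duration_min", "sum"),
                                       count=("duration_min", "size"))
    idx = pd.RangeIndex(recording_days, name="day")
    return grouped.reindex(idx, fill_value=0.0).astype({"count": int})


def peak_metrics(events: pd.DataFrame, recording_days: int) -> EcogSummary:
    """Daily totals for both kinds plus their peak values over recorded days."""
    sd = daily_totals(events, "SD", recording_days)
    sz = daily_totals(events, "seizure", recording_days)
    daily = pd.DataFrame({"TDDD": sd["total_min"], "SD_count": sd["count"],
                          "TSDD": sz["total_min"], "seizure_count": sz["count"]})
    return EcogSummary(daily=daily,
                       PTDDD=float(daily["TDDD"].max()),
                       peak_SD=int(daily["SD_count"].max()),
                       PTSDD=float(daily["TSDD"].max()),
                       peak_seizure=int(daily["seizure_count"].max()),
                       recording_days=recording_days)


def summarise_patient(events: pd.DataFrame, recording_days: int
                      ) -> tuple[EcogSummary, dict]:
    """Validate annotations, then compute the burden metrics."""
    valid, report = validate_events(events)
    return peak_metrics(valid, recording_days), report
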