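"""Sessionization: reconstruct reading sessions from decision timestamps.

A reader's time-stamped decision stream is cut into sessions wherever the
gap between consecutive decisions reaches the break threshold.  Position in
session (1-based) is the proxy for time on task, and the gap to the
previous decision within a session is the per-case reading time.  A gap of
exactly the threshold counts as a break (the threshold is a minimum idle
time).  The same stream segmented under a larger threshold yields sessions
that are exact concatenations of the smaller-threshold sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreakDefinition",
    "segment_sessions",
    "apply_exclusions",
    "included",
    "exclusion_audit",
    "position_bin",
    "POSITION_BIN_EDGES",
]

#: Position-in-session bins used for the binned accuracy analyses:
#: bin 1 = positions 2-30, bin 2 = 31-60, bin 3 = 61-90, bin 4 = 91-200.
POSITION_BIN_EDGES = (2, 30, 60, 90, 200)


@dataclass(frozen=True)
class BreakDefinition:
    """Minimum idle time (minutes) between decisions that counts as a break."""

    threshold_minutes: float = 20.0

    def __post_init__(self) -> None:
        if self.threshold_minutes <= 0:
            raise ValueError("threshold_minutes must be positive")

    @property
    def threshold_seconds(self) -> float:
        return self.threshold_minutes * 60.0


def segment_sessions(events: pd.DataFrame, breakdef: BreakDefinition) -> pd.DataFrame:
    """Annotate an event stream with session id, position and reading time.

    ``events`` must be sorted by (reader_id, decision_timestamp) with
    timestamps unique within each reader.  A new session starts at the
    first event of each reader and whenever the gap to the reader's
    previous decision is >= the break threshold.  Adds columns:

    * ``session_id`` — deterministic "<reader>-<k>" label,
    * ``position`` — 1-based position within session,
    * ``reading_time_seconds`` — gap to the previous decision within the
      session; missing (NaN) at position 1,
    * ``session_size`` — number of events in the session,
    * ``preceding_break_minutes`` — idle gap that opened the session;
      missing for the first session in a reader's stream.
    """
    required = {"reader_id", "decision_timestamp"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events missing required columns: {sorted(missing)}")
    reader = events["reader_id"].to_numpy()
    ts = events["decision_timestamp"].to_numpy(dtype=float)

    same_reader = np.r_[False, reader[1:] == reader[:-1]]
    gap = np.r_[np.nan, np.diff(ts)]
    gap[~same_reader] = np.nan
    # each reader id must occupy one contiguous block of rows
    first_pos = pd.Series(np.arange(len(reader))).groupby(reader, sort=False).min()
    last_pos = pd.Series(np.arange(len(reader))).groupby(reader, sort=False).max()
    counts = pd.Series(np.arange(len(reader))).groupby(reader, sort=False).count()
    if not ((last_pos - first_pos + 1) == counts).all():
        raise ValueError("events must be sorted by (reader_id, decision_timestamp)")
    bad = same_reader & (np.r_[np.nan, np.diff(ts)] < 0)
    if bad.any():
        r = reader[np.argmax(bad)]
        raise ValueError(f"timestamps not sorted for reader {r!r}")
    dup = same_reader & (np.r_[np.nan, np.diff(ts)] == 0)
    if dup.any():
        r = reader[np.argmax(dup)]
        raise ValueError(f"duplicate decision timestamps for reader {r!r}")

    is_break = same_reader & (gap >= breakdef.threshold_seconds)
    new_session = ~same_reader | is_break
    session_ord = np.cumsum(new_session)  # global 1-based session counter
    out = events.copy()
    # per-reader session index for deterministic ids
    sess_start_idx = np.flatnonzero(new_session)
    reader_of_sess = reader[sess_start_idx]
    per_reader_idx = np.zeros(len(sess_start_idx), dtype=np.int64)
    counter: dict = {}
    for i, r in enumerate(reader_of_sess):
        counter[r] = counter.get(r, 0) + 1
        per_reader_idx[i] = counter[r]
    sess_of_event = session_ord - 1  # 0-based index into session arrays
    out["session_id"] = [
        f"{reader_of_sess[s]}-{per_reader_idx[s]}" for s in sess_of_event
    ]
    position = np.arange(len(events)) - sess_start_idx[sess_of_event] + 1
    out["position"] = position
    rt = gap.copy()
    rt[new_session] = np.nan
    out["reading_time_seconds"] = rt
    sizes = np.bincount(sess_of_event)
    out["session_size"] = sizes[sess_of_event]
    preceding = np.full(len(sess_start_idx), np.nan)
    opened_by_break = is_break[sess_start_idx]
    preceding[opened_by_break] = gap[sess_start_idx[opened_by_break]] / 60.0
    out["preceding_break_minutes"] = preceding[sess_of_event]
    return out


_ACCURACY_REASONS = (
    ("first_in_session", lambda df: df["position"] == 1),
    ("position_over_200", lambda df: df["position"] > 200),
    ("moved", lambda df: df["moved"].astype(bool) if "moved" in df else np.zeros(len(df), bool)),
    (
        "second_reader",
        lambda df: (df["reader_role"] == "second")
        if "reader_role" in df
        else np.zeros(len(df), bool),
    ),
)
_TIME_REASONS = (
    ("time_over_10min", lambda df: df["reading_time_seconds"] > 600.0),
    ("time_zero", lambda df: df["reading_time_seconds"] == 0.0),
)


def apply_exclusions(records: pd.DataFrame, for_time_model: bool = False) -> pd.DataFrame:
    """Flag records excluded from analysis; nothing is dropped.

    Adds an ``excluded_reasons`` column (semicolon-joined, empty when the
    record is analysable).  Always flagged: position 1 (reading time
    undefined and the first case may differ systematically), position >
    200 (influential outliers), moved cases (not read in intended order)
    and second-reader decisions (only independent first reads are
    analysed).  With ``for_time_model`` the reading-time exclusions
    (> 600 s, or recorded as 0) are applied as well.

    Use :func:`included` to keep the analysable subset and
    :func:`exclusion_audit` for the per-reason counts.
    """
    if "position" not in records.columns:
        raise ValueError("records must be positioned (run segment_sessions first)")
    reasons = list(_ACCURACY_REASONS)
    if for_time_model:
        reasons += list(_TIME_REASONS)
    out = records.copy()
    tags = np.array([""] * len(out), dtype=object)
    for name, rule in reasons:
        mask = np.asarray(rule(out))
        mask = np.where(pd.isna(mask), False, mask).astype(bool)
        tags[mask] = np.where(tags[mask] == "", name, tags[mask] + ";" + name)
    out["excluded_reasons"] = tags
    return out


def included(records: pd.DataFrame) -> pd.DataFrame:
    """Subset of records with no exclusion reason."""
    if "excluded_reasons" not in records.columns:
        raise ValueError("run apply_exclusions first")
    return records[records["excluded_reasons"] == ""].copy()


def exclusion_audit(records: pd.DataFrame) -> pd.Series:
    """Count of records carrying each exclusion reason (reasons can co-occur)."""
    if "excluded_reasons" not in records.columns:
        raise ValueError("run apply_exclusions first")
    counts: dict[str, int] = {"included": int((records["excluded_reasons"] == "").sum())}
    for tags in records.loc[records["excluded_reasons"] != "", "excluded_reasons"]:
        for t in tags.split(";"):
            counts[t] = counts.get(t, 0) + 1
    return pd.Series(counts, dtype=int)


def position_bin(position: int) -> int:
    """Map analysis position (2..200) to its accuracy bin (1..4)."""
    if not 2 <= position <= 200:
        raise ValueError(f"position {position} outside the analysis range [2, 200]")
    if position <= 30:
        return 1
    if position <= 60:
        return 2
    if position <= 90:
        return 3
    return 4


def position_bin_array(positions) -> np.ndarray:
    """Vectorised :func:`position_bin`."""
    p = np.asarray(positions)
    if np.any((p < 2) | (p > 200)):
        raise ValueError("positions outside the analysis range [2, 200]")
    return np.digitize(p, [31, 61, 91]) + 1
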