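"""Confound-robustness analyses for the time-on-task curves.

Declining recall with position could in principle reflect properties of
the women listed late in a session, or of the readers who choose to read
long sessions, rather than a within-reader criterion shift.  These checks
separate the explanations:

* forward/reverse comparison — in the intervention arm the two readers
  traverse the same list in opposite orders, so a woman-level gradient
  reverses sign between directions while a reader-level drift does not;
* minimum-session-length stratification — fixing session length removes
  amalgamation effects from readers with different session habits;
* break-length-band analysis — start-of-session accuracy as a function of
  the preceding break length (criterion reset is partial after short
  breaks);
* moved-case sensitivity — curves with and without cases read out of
  intended order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import accuracy_summary, confusion_counts, sdt_summary, wilson_interval
from .sessions import BreakDefinition, segment_sessions

__all__ = [
    "forward_reverse_comparison",
    "min_session_length_stratification",
    "break_band_analysis",
    "moved_case_sensitivity",
    "position_curves",
    "BREAK_BANDS_HOURS",
]

#: Break-length bands (hours) for the band analysis.
BREAK_BANDS_HOURS = ((0.0, 1.0), (1.0, 3.0), (3.0, 12.0), (12.0, np.inf))


def position_curves(records: pd.DataFrame, max_position: int | None = None) -> pd.DataFrame:
    """Recall rate, cancer detection rate and mean time per position.

    One tidy row per (position, metric); rate metrics carry Wilson CIs,
    mean time a normal-approximation interval.
    """
    df = records
    if max_position is not None:
        df = df[df["position"] <= max_position]
    recall = (df["decision"] == "recall").astype(int)
    tp = (recall.astype(bool) & (df["cancer_status"] != "none")).astype(int)
    t = df["reading_time_seconds"]
    g = pd.DataFrame(
        {"position": df["position"], "recall": recall, "tp": tp, "time": t}
    ).groupby("position")
    rows = []
    for pos, sub in g:
        n = len(sub)
        for metric, k in (("recall_rate", int(sub["recall"].sum())), ("cancer_detection_rate", int(sub["tp"].sum()))):
            lo, hi = wilson_interval(k, n)
            rows.append(
                {"position": int(pos), "metric": metric, "value": k / n, "ci_low": lo, "ci_high": hi, "n": n}
            )
        times = sub["time"].dropna()
        if len(times):
            m = float(times.mean())
            se = float(times.std(ddof=1) / np.sqrt(len(times))) if len(times) > 1 else np.nan
            rows.append(
                {
                    "position": int(pos),
                    "metric": "mean_time_seconds",
                    "value": m,
                    "ci_low": m - 1.96 * se,
                    "ci_high": m + 1.96 * se,
                    "n": int(len(times)),
                }
            )
    return pd.DataFrame(rows)


def forward_reverse_comparison(
    events: pd.DataFrame,
    breakdef: BreakDefinition = BreakDefinition(20.0),
    max_position: int = 60,
) -> pd.DataFrame:
    """Position curves separately for forward- and reverse-direction reads.

    Uses intervention-arm events only (both reader roles — the point is
    the traversal direction, not independence), truncated at
    ``max_position``.  If a woman-level position gradient drove the
    curves, the two directions would trend oppositely; a reader-level
    drift gives the same trend in both.
    """
    if "direction" not in events.columns or events["direction"].isna().any():
        raise ValueError("events must carry direction labels")
    sub = events[events["arm"] == "intervention"]
    if len(sub) == 0:
        raise ValueError("no intervention-arm events to compare")
    positioned = segment_sessions(
        sub.sort_values(["reader_id", "decision_timestamp"], kind="mergesort").reset_index(drop=True),
        breakdef,
    )
    positioned = positioned[(positioned["position"] >= 2) & (positioned["position"] <= 200)]
    frames = []
    for direction in ("forward", "reverse"):
        strat = positioned[positioned["direction"] == direction]
        curves = position_curves(strat, max_position=max_position)
        curves.insert(0, "stratum", direction)
        frames.append(curves)
    return pd.concat(frames, ignore_index=True)


def min_session_length_stratification(
    records: pd.DataFrame, min_lengths: list[int]
) -> pd.DataFrame:
    """Position curves restricted to sessions of at least each minimum size.

    A session "longer than the minimum task length" is taken inclusively
    (size >= min length).  An empty stratum yields no rows but is still
    recorded in the output's attrs under ``empty_strata``.
    """
    frames = []
    empty = []
    for m in min_lengths:
        strat = records[records["session_size"] >= m]
        if len(strat) == 0:
            empty.append(m)
            continue
        curves = position_curves(strat)
        curves.insert(0, "stratum", f"min_length_{m}")
        frames.append(curves)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["stratum", "position", "metric", "value", "ci_low", "ci_high", "n"])
    )
    out.attrs["empty_strata"] = empty
    return out


def break_band_analysis(
    records: pd.DataFrame,
    bands_hours: tuple[tuple[float, float], ...] = BREAK_BANDS_HOURS,
) -> pd.DataFrame:
    """Start-of-session accuracy and SDT statistics by preceding break length.

    Uses bin-1 records (positions 2-30) of sessions whose preceding break
    falls in each band.  A session opening a reader's stream has no
    observed break and is treated as following a long (> 12 h) break.
    Returns tidy rows of specificity, sensitivity, d' and criterion per
    band.
    """
    sub = records[(records["position"] >= 2) & (records["position"] <= 30)]
    brk = sub["preceding_break_minutes"].to_numpy(dtype=float) / 60.0
    # a session opening the stream has no observed break: treat as very long
    brk = np.where(np.isnan(brk), 1e300, brk)
    rows = []
    for lo, hi in bands_hours:
        label = f"{lo:g}-{hi:g}h" if np.isfinite(hi) else f">{lo:g}h"
        band_records = sub[(brk >= lo) & (brk < hi)]
        if len(band_records) == 0:
            continue
        counts = confusion_counts(band_records)
        acc = accuracy_summary(counts)
        for name in ("sensitivity", "specificity"):
            est = acc[name]
            if est is not None:
                rows.append(
                    {
                        "band": label,
                        "metric": name,
                        "value": est.value,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "n": est.n,
                    }
                )
        if counts.n_cancer > 0 and counts.n_normal > 0:
            s = sdt_summary(counts)
            rows.append(
                {"band": label, "metric": "d_prime", "value": s.d_prime, "ci_low": s.d_prime_ci[0], "ci_high": s.d_prime_ci[1], "n": counts.total}
            )
            rows.append(
                {"band": label, "metric": "criterion", "value": s.criterion, "ci_low": s.criterion_ci[0], "ci_high": s.criterion_ci[1], "n": counts.total}
            )
    return pd.DataFrame(rows)


def moved_case_sensitivity(
    records_all: pd.DataFrame, records_excluding_moved: pd.DataFrame
) -> pd.DataFrame:
    """Paired position curves with and without moved cases.

    Returns the merged curves with a ``difference`` column (with - without)
    per (position, metric).  If the excluding arm is empty the result is
    flagged via attrs["empty_excluding_arm"].
    """
    with_moved = position_curves(records_all)
    out_flag = len(records_excluding_moved) == 0
    if out_flag:
        merged = with_moved.rename(columns={"value": "value_with_moved"})
        merged["value_without_moved"] = np.nan
        merged["difference"] = np.nan
    else:
        without = position_curves(records_excluding_moved)
        merged = with_moved.merge(
            without,
            on=["position", "metric"],
            suffixes=("_with_moved", "_without_moved"),
        )
        merged["difference"] = (
            merged["value_with_moved"] - merged["value_without_moved"]
        )
    merged.attrs["empty_excluding_arm"] = out_flag
    return merged
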