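"""Sessionization against a brute-force oracle, plus exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from vigilread import BreakDefinition, apply_exclusions, exclusion_audit, included, position_bin, segment_sessions
from vigilread.sessions import position_bin_array


def brute_force_sessions(timestamps, threshold_minutes):
    """Independent segmentation written directly from the break definition:
    walk the stream, starting a new session whenever the idle gap is at
    least the threshold.  Returns (session index, position) per event."""
    sessions, positions = [], []
    sess, pos = 0, 0
    for i, t in enumerate(timestamps):
        if i == 0 or t - timestamps[i - 1] >= threshold_minutes * 60:
            sess += 1
            pos = 1
        else:
            pos += 1
        sessions.append(sess)
        positions.append(pos)
    return sessions, positions


def _stream_frame(streams):
    frames = []
    for reader, ts in streams.items():
        frames.append(pd.DataFrame({"reader_id": reader, "decision_timestamp": ts}))
    return pd.concat(frames, ignore_index=True)


def test_worked_example_gap_stream():
    """Gaps of [1, 1, 30, 1] minutes split at a 20-min threshold but not 60."""
    ts = np.cumsum([0.0, 60, 60, 1800, 60])
    df = pd.DataFrame({"reader_id": "A", "decision_timestamp": ts})
    out20 = segment_sessions(df, BreakDefinition(20))
    assert out20["position"].tolist() == [1, 2, 3, 1, 2]
    assert out20["session_id"].nunique() == 2
    out60 = segment_sessions(df, BreakDefinition(60))
    assert out60["position"].tolist() == [1, 2, 3, 4, 5]
    assert out60["session_id"].nunique() == 1


def test_gap_of_exactly_threshold_is_a_break():
    ts = np.array([0.0, 1200.0, 1260.0])
    out = segment_sessions(pd.DataFrame({"reader_id": 1, "decision_timestamp": ts}), BreakDefinition(20))
    assert out["position"].tolist() == [1, 1, 2]


def test_random_streams_match_brute_force(rng):
    thresholds = [10, 20, 60, 180, 480]
    for _ in range(200):
        n = int(rng.integers(1, 51))
        gaps = rng.choice([30.0, 300.0, 700.0, 1500.0, 4000.0, 40000.0], size=n - 1) * rng.uniform(0.5, 1.5, size=max(n - 1, 0))
        ts = np.r_[0.0, np.cumsum(gaps)]
        df = pd.DataFrame({"reader_id": "r", "decision_timestamp": ts})
        boundaries = {}
        for t in thresholds:
            out = segment_sessions(df, BreakDefinition(t))
            sess, pos = brute_force_sessions(ts, t)
            got_sess = pd.factorize(out["session_id"])[0] + 1
            assert got_sess.tolist() == sess
            assert out["position"].tolist() == pos
            boundaries[t] = set(np.flatnonzero(out["position"].to_numpy() == 1))
        # nesting: boundaries under a larger threshold are a subset
        for t1, t2 in zip(thresholds, thresholds[1:]):
            assert boundaries[t2] <= boundaries[t1]


def test_reading_time_is_within_session_gap():
    ts = np.cumsum([0.0, 45, 50, 3000, 70])
    out = segment_sessions(pd.DataFrame({"reader_id": "x", "decision_timestamp": ts}), BreakDefinition(20))
    rt = out["reading_time_seconds"].tolist()
    assert np.isnan(rt[0]) and np.isnan(rt[3])  # position 1 has no reading time
    assert rt[1:3] == [45.0, 50.0]
    assert rt[4] == 70.0
    assert out["preceding_break_minutes"].iloc[3] == pytest.approx(50.0)


def test_unsorted_and_duplicate_streams_rejected():
    df = pd.DataFrame({"reader_id": ["a", "a"], "decision_timestamp": [10.0, 5.0]})
    with pytest.raises(ValueError, match="not sorted for reader 'a'"):
        segment_sessions(df, BreakDefinition(20))
    df = pd.DataFrame({"reader_id": ["b", "b"], "decision_timestamp": [5.0, 5.0]})
    with pytest.raises(ValueError, match="duplicate decision timestamps for reader 'b'"):
        segment_sessions(df, BreakDefinition(20))
    interleaved = pd.DataFrame(
        {"reader_id": ["a", "b", "a"], "decision_timestamp": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(ValueError, match="sorted by"):
        segment_sessions(interleaved, BreakDefinition(20))


def test_every_event_appears_once(default_cohort):
    _, _, events = default_cohort
    out = segment_sessions(events, BreakDefinition(20))
    assert len(out) == len(events)
    assert out.groupby("session_id")["position"].apply(
        lambda p: (p.to_numpy() == np.arange(1, len(p) + 1)).all()
    ).all()


def _positioned(n=250):
    ts = np.arange(n) * 60.0
    df = pd.DataFrame(
        {
            "reader_id": "r",
            "decision_timestamp": ts,
            "moved": False,
            "reader_role": "first",
        }
    )
    return segment_sessions(df, BreakDefinition(20))


def test_exclusion_reasons():
    flagged = apply_exclusions(_positioned())
    by_pos = flagged.set_index("position")["excluded_reasons"]
    assert by_pos.loc[1] == "first_in_session"
    assert by_pos.loc[201] == "position_over_200"
    assert by_pos.loc[150] == ""
    audit = exclusion_audit(flagged)
    assert audit["included"] == 199
    assert audit["position_over_200"] == 50
    # conservation: every record either included or carries >= 1 reason
    assert audit["included"] + (flagged["excluded_reasons"] != "").sum() == len(flagged)


def test_time_exclusions_only_for_time_model():
    pos = _positioned(10)
    pos.loc[pos["position"] == 5, "reading_time_seconds"] = 601.0
    pos.loc[pos["position"] == 6, "reading_time_seconds"] = 0.0
    accuracy = apply_exclusions(pos, for_time_model=False)
    assert accuracy.set_index("position")["excluded_reasons"].loc[5] == ""
    time = apply_exclusions(pos, for_time_model=True)
    assert time.set_index("position")["excluded_reasons"].loc[5] == "time_over_10min"
    assert time.set_index("position")["excluded_reasons"].loc[6] == "time_zero"


def test_moved_and_second_reader_excluded():
    pos = _positioned(10)
    pos["moved"] = [False] * 9 + [True]
    pos["reader_role"] = ["first"] * 8 + ["second"] * 2
    flagged = apply_exclusions(pos)
    assert "moved" in flagged["excluded_reasons"].iloc[9]
    assert "second_reader" in flagged["excluded_reasons"].iloc[8]
    kept = included(flagged)
    assert len(kept) == 7  # position 1, two second-reader, one moved (overlapping)


def test_empty_input_round_trips():
    pos = _positioned(3).iloc[:0]
    flagged = apply_exclusions(pos)
    assert len(flagged) == 0
    assert len(included(flagged)) == 0


@pytest.mark.parametrize(
    "position,expected", [(2, 1), (30, 1), (31, 2), (60, 2), (61, 3), (90, 3), (91, 4), (200, 4)]
)
def test_position_bins(position, expected):
    assert position_bin(position) == expected


def test_position_bin_rejects_out_of_range():
    for bad in (1, 0, 201):
        with pytest.raises(ValueError):
            position_bin(bad)
    with pytest.raises(ValueError):
        position_bin_array([2, 1])
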