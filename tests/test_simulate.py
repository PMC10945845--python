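"""Cohort generator: calibration margins, determinism and structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vigilread import SimConfig, criterion_at, sample_reading_time, simulate_cohort
from vigilread.sessions import BreakDefinition, position_bin_array, segment_sessions
from vigilread.simulate import ReaderProfile, gamma_shape_for_ratio, reset_fraction_for_break


def _profile(dev=0.0):
    return ReaderProfile(0, 0, dev, 0.0, 2.787)


class TestCriterionDrift:
    def test_full_reset_returns_to_base(self):
        cfg = SimConfig()
        c = criterion_at(_profile(), cfg, 1, preceding_break_minutes=600.0, accumulated_drift=0.5)
        assert c == pytest.approx(cfg.criterion_base)

    def test_zero_drift_is_position_invariant(self):
        cfg = dataclasses.replace(SimConfig(), criterion_drift_per_case=0.0)
        vals = {criterion_at(_profile(0.1), cfg, p) for p in (1, 50, 200)}
        assert len(vals) == 1

    def test_linear_accumulation(self):
        cfg = dataclasses.replace(SimConfig(), criterion_drift_per_case=0.002)
        c = criterion_at(_profile(), cfg, 101)
        assert c == pytest.approx(cfg.criterion_base + 0.200)

    def test_partial_reset_scales_carry(self):
        cfg = SimConfig()  # 20-60 min band resets 70% of the carry
        c = criterion_at(_profile(), cfg, 1, preceding_break_minutes=30.0, accumulated_drift=0.2)
        assert c == pytest.approx(cfg.criterion_base + 0.2 * 0.3)

    def test_unknown_band_names_boundaries(self):
        cfg = dataclasses.replace(
            SimConfig(), reset_fraction_by_break_band={(0.0, 20.0): 0.0, (480.0, np.inf): 1.0}
        )
        with pytest.raises(ValueError, match="band boundaries"):
            reset_fraction_for_break(cfg, 100.0)


class TestReadingTime:
    def test_mean_at_session_start(self, rng):
        x = sample_reading_time(SimConfig(), 1, "TN", rng, size=200_000)
        assert x.mean() == pytest.approx(73.7, rel=0.01)

    def test_median_to_mean_ratio(self, rng):
        x = sample_reading_time(SimConfig(), 1, "TN", rng, size=200_000)
        assert np.median(x) / x.mean() == pytest.approx(36 / 69, abs=0.03)

    def test_mean_declines_to_position_200(self, rng):
        x = sample_reading_time(SimConfig(), 200, "TN", rng, size=100_000)
        assert x.mean() == pytest.approx(55.1, rel=0.02)

    def test_constant_config_is_position_invariant(self, rng):
        cfg = dataclasses.replace(
            SimConfig(), time_mean_start=60.0, time_mean_at_200=60.0, recall_time_offset_seconds=0.0
        )
        a = sample_reading_time(cfg, 1, "TN", rng, size=100_000)
        b = sample_reading_time(cfg, 150, "TP", rng, size=100_000)
        assert a.mean() == pytest.approx(b.mean(), rel=0.02)

    def test_recall_offset_raises_mean(self, rng):
        cfg = SimConfig()
        tn = sample_reading_time(cfg, 1, "TN", rng, size=50_000)
        tp = sample_reading_time(cfg, 1, "TP", rng, size=50_000)
        assert tp.mean() > tn.mean()

    def test_shape_solver_hits_ratio(self):
        from scipy import special

        k = gamma_shape_for_ratio(36 / 69)
        assert special.gammaincinv(k, 0.5) / k == pytest.approx(36 / 69, abs=1e-8)

    def test_invalid_means_rejected(self, rng):
        cfg = dataclasses.replace(SimConfig(), time_mean_start=80.0, time_mean_at_200=90.0)
        with pytest.raises(ValueError):
            cfg.validate()


class TestCohortStructure:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_women=3000, n_readers=10, n_centers=4, seed=9)
        w1, e1 = simulate_cohort(cfg)
        w2, e2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_every_woman_read_once_per_role(self, default_cohort):
        cfg, women, events = default_cohort
        for role in ("first", "second"):
            sub = events[events["reader_role"] == role]
            assert len(sub) == cfg.n_women
            assert sub["woman_id"].nunique() == cfg.n_women

    def test_zero_prevalence_means_no_cancer_outcomes(self):
        cfg = SimConfig(
            n_women=3000,
            n_readers=10,
            n_centers=4,
            prevalence_screen_detectable=0.0,
            prevalence_interval=0.0,
            seed=3,
        )
        women, events = simulate_cohort(cfg)
        assert (women["cancer_status"] == "none").all()

    def test_marginals_match_configuration(self, default_cohort):
        cfg, women, events = default_cohort
        n = cfg.n_women
        assert women["age"].mean() == pytest.approx(cfg.age_mean, abs=0.2)
        assert women["first_screen"].mean() == pytest.approx(cfg.prop_first_screen, abs=0.02)
        prev = (women["cancer_status"] == "screen_detectable").mean()
        tol = 4 * np.sqrt(cfg.prevalence_screen_detectable / n)
        assert prev == pytest.approx(cfg.prevalence_screen_detectable, abs=tol)

    def test_intervention_second_reader_reverses_order(self, default_cohort):
        _, _, events = default_cohort
        sub = events[(events["arm"] == "intervention") & (events["reader_role"] == "second")]
        assert (sub["direction"] == "reverse").all()
        fwd = events[events["direction"] == "forward"]
        assert len(fwd) > 0

    def test_timestamps_strictly_increasing_per_reader(self, default_cohort):
        _, _, events = default_cohort
        for _, sub in events.groupby("reader_id"):
            assert (np.diff(sub["decision_timestamp"].to_numpy()) > 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_women"):
            SimConfig(n_women=10, n_readers=50).validate()
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(break_length_mixture=[((0.0, 20.0), 0.5)]).validate()


def test_recall_rate_declines_with_position(default_cohort):
    """With positive criterion drift and constant d', recall probability is
    non-increasing in position: early bins recall more than late bins."""
    _, women, events = default_cohort
    first = events[events["reader_role"] == "first"].merge(women, on="woman_id")
    positioned = segment_sessions(
        first.sort_values(["reader_id", "decision_timestamp"], kind="mergesort").reset_index(drop=True),
        BreakDefinition(20.0),
    )
    sub = positioned[(positioned["position"] >= 2) & (positioned["position"] <= 200)]
    bins = position_bin_array(sub["position"].to_numpy())
    recall = (sub["decision"] == "recall").to_numpy()
    rate_by_bin = [recall[bins == b].mean() for b in (1, 4)]
    assert rate_by_bin[0] > rate_by_bin[1]
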