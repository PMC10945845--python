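"""Synthetic reader-behaviour generator for double-read screening programmes.

The generator emulates the structure of an English breast-screening reading
stream: women are grouped into intended sessions (daily lists, median ~35
women), each session is examined independently by two readers, and in the
intervention arm the second reader traverses the list in reverse order.
Decisions follow the equal-variance signal-detection model of the
multiple-decision account of visual search applied to time on task:

* discriminability d' is constant within a reader,
* the decision criterion drifts up linearly with every case examined
  (readers become more conservative, i.e. less willing to recall),
* a rest break resets the accumulated drift partially or fully depending on
  the break length band (only the longest band gives a full reset),
* reading time per case is gamma distributed with a log-mean that declines
  linearly from position 1 to position 200.

Two generators are provided: :func:`simulate_cohort` produces the full
event stream (timestamps, recall decisions, session structure) used by the
sessionization and metrics layers, and :func:`simulate_records_glmm` draws
records directly from a logistic or gamma mixed model with known
coefficients, for parameter-recovery studies of the model-fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import norm, truncnorm

from .sdt import hit_false_alarm_rates

__all__ = [
    "SimConfig",
    "ReaderProfile",
    "simulate_cohort",
    "simulate_records_glmm",
    "criterion_at",
    "sample_reading_time",
    "gamma_shape_for_ratio",
    "hit_false_alarm_rates",
]

BreakBand = tuple[float, float]

#: Break-length bands (minutes) and the fraction of accumulated criterion
#: drift that a break in that band wipes out.  Only a full night away from
#: the workstation (>480 min) resets the criterion completely; shorter
#: breaks reset it partially, which reproduces the start-of-session recall
#: rate sitting below the start-of-day recall rate.
DEFAULT_RESET_FRACTIONS: dict[BreakBand, float] = {
    (0.0, 20.0): 0.0,
    (20.0, 60.0): 0.7,
    (60.0, 180.0): 0.7,
    (180.0, 480.0): 0.7,
    (480.0, math.inf): 1.0,
}

#: Mixture over idle gaps between consecutive intended sessions in a
#: reader's stream.  Most gaps are short enough not to count as a break
#: under the 20-min definition, so a working day contains several
#: multi-session reading runs; one gap in ten is an overnight break.
DEFAULT_BREAK_MIXTURE: list[tuple[BreakBand, float]] = [
    ((0.5, 15.0), 0.55),
    ((20.0, 60.0), 0.15),
    ((60.0, 180.0), 0.12),
    ((180.0, 480.0), 0.08),
    ((480.0, 1440.0), 0.10),
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults are calibrated to the English programme's published margins:
    0.82% of women have cancer detected at screening, ~0.2% have interval
    cancers within 3 years, 21% attend their first-ever screen, mean age
    59, reading takes a mean of ~74 s at the start of a session declining
    to ~55 s by the 200th case, with a median/mean ratio of 36/69, and
    intended sessions have median size 35.
    """

    n_readers: int = 50
    n_centers: int = 10
    n_women: int = 20_000
    prevalence_screen_detectable: float = 0.0099
    prevalence_interval: float = 0.0020
    prop_first_screen: float = 0.21
    age_mean: float = 59.0
    age_sd: float = 5.5
    age_range: tuple[float, float] = (47.0, 73.0)
    d_prime_base: float = 2.787
    criterion_base: float = 0.34
    criterion_drift_per_case: float = 0.001
    reset_fraction_by_break_band: dict[BreakBand, float] = field(
        default_factory=lambda: dict(DEFAULT_RESET_FRACTIONS)
    )
    time_mean_start: float = 73.7
    time_mean_at_200: float = 55.1
    time_median_to_mean_ratio: float = 36.0 / 69.0
    recall_time_offset_seconds: float = 15.0
    session_size_median: int = 35
    session_size_sigma: float = 0.35
    break_length_mixture: list[tuple[BreakBand, float]] = field(
        default_factory=lambda: list(DEFAULT_BREAK_MIXTURE)
    )
    arm_split: float = 0.5
    moved_fraction: float = 0.01
    # Reader heterogeneity (random-intercept SDs on criterion and log time).
    criterion_reader_sd: float = 0.08
    log_time_reader_sd: float = 0.10
    d_prime_reader_sd: float = 0.0
    # Woman-level confound: slope on intended order index added to the
    # criterion, so early-listed women are systematically easier to recall.
    # Zero by default (the programme's allocation gives no such gradient);
    # used by the robustness discriminator tests.
    woman_position_effect: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        props = {
            "prevalence_screen_detectable": self.prevalence_screen_detectable,
            "prevalence_interval": self.prevalence_interval,
            "prop_first_screen": self.prop_first_screen,
            "arm_split": self.arm_split,
            "moved_fraction": self.moved_fraction,
            "time_median_to_mean_ratio": self.time_median_to_mean_ratio,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} must lie in [0, 1]")
        if self.prevalence_screen_detectable + self.prevalence_interval >= 1.0:
            raise ValueError("total cancer prevalence must be < 1")
        if self.time_mean_at_200 > self.time_mean_start:
            raise ValueError("time_mean_at_200 must be <= time_mean_start")
        if self.time_mean_at_200 <= 0 or self.time_mean_start <= 0:
            raise ValueError("configured mean reading times must be positive")
        weights = [w for _, w in self.break_length_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("break_length_mixture weights must sum to 1")
        for (lo, hi), frac in self.reset_fraction_by_break_band.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"reset fraction {frac} for band ({lo}, {hi}) not in [0, 1]")
            if lo >= hi:
                raise ValueError(f"break band ({lo}, {hi}) is empty")
        if self.d_prime_base < 0:
            raise ValueError("d_prime_base must be >= 0")
        if self.n_readers < 2 * self.n_centers:
            raise ValueError("need at least two readers per center for double reading")
        if self.n_women < self.n_readers:
            raise ValueError(
                f"n_women={self.n_women} must be >= n_readers={self.n_readers}"
            )


@dataclass(frozen=True)
class ReaderProfile:
    """One reader's random effects around the population parameters."""

    reader_id: int
    center_id: int
    criterion_intercept_deviation: float
    log_time_intercept_deviation: float
    d_prime: float

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValueError("d_prime must be >= 0")


def reset_fraction_for_break(config: SimConfig, break_minutes: float) -> float:
    """Fraction of accumulated criterion drift wiped out by a break."""
    for (lo, hi), frac in config.reset_fraction_by_break_band.items():
        if lo <= break_minutes < hi:
            return frac
    bands = sorted(config.reset_fraction_by_break_band)
    raise ValueError(
        f"break of {break_minutes} min falls in no configured band; "
        f"configured band boundaries (minutes): {bands}"
    )


def criterion_at(
    profile: ReaderProfile,
    config: SimConfig,
    position: int,
    preceding_break_minutes: float | None = None,
    accumulated_drift: float = 0.0,
) -> float:
    """Decision criterion at a within-session position.

    The criterion drifts up by ``criterion_drift_per_case`` with every case
    examined.  ``accumulated_drift`` is the drift carried over from earlier
    sessions; a preceding break multiplies it by (1 - reset fraction) for
    the matching break band, so the longest band restores the criterion to
    its base value.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    carry = accumulated_drift
    if preceding_break_minutes is not None:
        carry *= 1.0 - reset_fraction_for_break(config, preceding_break_minutes)
    return (
        config.criterion_base
        + profile.criterion_intercept_deviation
        + carry
        + config.criterion_drift_per_case * (position - 1)
    )


def gamma_shape_for_ratio(median_to_mean: float) -> float:
    """Gamma shape parameter whose median/mean ratio matches the target.

    For shape k the ratio is gammaincinv(k, 1/2) / k, monotone increasing
    in k; solved once per configuration by bisection.
    """
    if not 0.0 < median_to_mean < 1.0:
        raise ValueError("median/mean ratio must lie in (0, 1)")

    def f(k: float) -> float:
        return special.gammaincinv(k, 0.5) / k - median_to_mean

    return float(optimize.brentq(f, 1e-3, 200.0, xtol=1e-10))


def _log_mean_time(config: SimConfig, position: np.ndarray | int) -> np.ndarray:
    """Log mean reading time, linear in log-mean over positions 1..200."""
    p = np.minimum(np.asarray(position, dtype=float), 200.0)
    lo = math.log(config.time_mean_start)
    hi = math.log(config.time_mean_at_200)
    return lo + (hi - lo) * (p - 1.0) / 199.0


def sample_reading_time(
    config: SimConfig,
    position: int,
    outcome_kind: Literal["TP", "FP", "TN", "FN"],
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw per-case reading time(s) in seconds.

    Right-skewed gamma draw whose mean interpolates ``time_mean_start`` to
    ``time_mean_at_200`` linearly in log-mean over positions 1..200 (held
    constant beyond 200), with a positive offset on the mean for recall
    decisions (TP/FP).  The gamma shape is solved so the median/mean ratio
    matches ``time_median_to_mean_ratio``.
    """
    if position < 1:
        raise ValueError("position must be >= 1")
    if config.time_mean_start <= 0 or config.time_mean_at_200 <= 0:
        raise ValueError("configured mean reading times must be positive")
    mean = float(np.exp(_log_mean_time(config, position)))
    if outcome_kind in ("TP", "FP"):
        mean += config.recall_time_offset_seconds
    shape = gamma_shape_for_ratio(config.time_median_to_mean_ratio)
    out = rng.gamma(shape, mean / shape, size=size)
    return float(out) if size is None else out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_women(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_women
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    age = np.round(age, 1)
    # First screens skew young: weight decays with age, rescaled to hit the
    # configured marginal proportion (slope mild enough that no probability
    # clips at 1, which would bias the marginal down)
    w = np.exp(-0.1 * (age - lo))
    p_first = np.clip(config.prop_first_screen * w / w.mean(), 0.0, 1.0)
    first_screen = rng.random(n) < p_first
    u = rng.random(n)
    status = np.where(
        u < config.prevalence_screen_detectable,
        "screen_detectable",
        np.where(
            u < config.prevalence_screen_detectable + config.prevalence_interval,
            "interval",
            "none",
        ),
    )
    return pd.DataFrame(
        {
            "woman_id": np.arange(n, dtype=np.int64),
            "age": age,
            "first_screen": first_screen,
            "cancer_status": status,
        }
    )


def _draw_reader_profiles(config: SimConfig, rng: np.random.Generator) -> list[ReaderProfile]:
    profiles = []
    for r in range(config.n_readers):
        dp = config.d_prime_base
        if config.d_prime_reader_sd > 0:
            dp = max(0.0, dp + config.d_prime_reader_sd * rng.standard_normal())
        profiles.append(
            ReaderProfile(
                reader_id=r,
                center_id=r % config.n_centers,
                criterion_intercept_deviation=config.criterion_reader_sd * rng.standard_normal(),
                log_time_intercept_deviation=config.log_time_reader_sd * rng.standard_normal(),
                d_prime=dp,
            )
        )
    return profiles


def _partition_sessions(config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Split woman indices into intended sessions (median ~35 women)."""
    sizes: list[int] = []
    total = 0
    mu = math.log(config.session_size_median)
    while total < config.n_women:
        s = int(round(float(rng.lognormal(mu, config.session_size_sigma))))
        s = max(s, 5)
        sizes.append(s)
        total += s
    sizes[-1] -= total - config.n_women
    if sizes[-1] < 1:
        sizes = sizes[:-1] if len(sizes) > 1 else [config.n_women]
        sizes[-1] = config.n_women - sum(sizes[:-1])
    order = rng.permutation(config.n_women)
    out, start = [], 0
    for s in sizes:
        out.append(order[start : start + s])
        start += s
    return out


def _sample_break_minutes(
    config: SimConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    bands = [b for b, _ in config.break_length_mixture]
    weights = np.array([w for _, w in config.break_length_mixture])
    idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    lo = np.array([bands[i][0] for i in idx])
    hi = np.array([bands[i][1] for i in idx])
    return lo + (hi - lo) * rng.random(n)


def _apply_moves(
    order: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap a small fraction of adjacent pairs; returns (new order, moved mask)."""
    n = len(order)
    moved = np.zeros(n, dtype=bool)
    if frac <= 0 or n < 2:
        return order, moved
    cand = rng.random(n - 1) < frac / 2.0
    # forbid overlapping swaps
    cand[1:] &= ~cand[:-1]
    idx = np.nonzero(cand)[0]
    new = order.copy()
    new[idx], new[idx + 1] = order[idx + 1], order[idx]
    moved[idx] = True
    moved[idx + 1] = True
    return new, moved


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a double-read screening cohort.

    Returns ``(women, events)``: a woman-level table (age, first-screen
    flag, 3-year reference-standard cancer status) and a time-stamped event
    stream in which every woman is examined once by a first reader and once
    by a second reader.  Reproducible: the same config (including seed)
    yields identical tables.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    women_ss, struct_ss, *reader_ss = ss.spawn(2 + config.n_readers)
    women = _draw_women(config, np.random.default_rng(women_ss))
    struct_rng = np.random.default_rng(struct_ss)
    profiles = _draw_reader_profiles(config, struct_rng)
    sessions = _partition_sessions(config, struct_rng)
    n_sessions = len(sessions)

    readers_by_center: dict[int, list[int]] = {}
    for p in profiles:
        readers_by_center.setdefault(p.center_id, []).append(p.reader_id)

    session_center = struct_rng.integers(0, config.n_centers, size=n_sessions)
    session_arm = np.where(
        struct_rng.random(n_sessions) < config.arm_split, "intervention", "control"
    )
    # pick a (first, second) reader pair from the session's center
    session_pairs = []
    for s in range(n_sessions):
        pool = readers_by_center[int(session_center[s])]
        pair = struct_rng.choice(len(pool), size=2, replace=False)
        session_pairs.append((pool[pair[0]], pool[pair[1]]))

    # per-reader assignment lists, in chronological (session index) order
    assignments: dict[int, list[tuple[int, str]]] = {p.reader_id: [] for p in profiles}
    for s, (r1, r2) in enumerate(session_pairs):
        assignments[r1].append((s, "first"))
        assignments[r2].append((s, "second"))

    status = women["cancer_status"].to_numpy()
    is_signal = status == "screen_detectable"
    shape = gamma_shape_for_ratio(config.time_median_to_mean_ratio)
    frames = []
    for profile in profiles:
        rng = np.random.default_rng(reader_ss[profile.reader_id])
        assigned = assignments[profile.reader_id]
        if not assigned:
            continue
        order_parts = []
        sess_meta = []  # (session_idx, role, length)
        for s, role in assigned:
            idx = sessions[s]
            if role == "second" and session_arm[s] == "intervention":
                idx = idx[::-1]
            idx, moved = _apply_moves(idx, config.moved_fraction, rng)
            order_parts.append((idx, moved))
            sess_meta.append((s, role, len(idx)))

        lengths = np.array([m[2] for m in sess_meta])
        n_ev = int(lengths.sum())
        breaks = _sample_break_minutes(config, rng, len(sess_meta))
        breaks[0] = np.nan  # no preceding break for the first session

        # criterion-drift and reading-time-decline carries across the stream;
        # both accumulate per case and are partially reset by breaks, the
        # time decline saturating at its position-200 level
        carry = np.empty(len(sess_meta))
        time_carry = np.empty(len(sess_meta))
        decline_rate = (
            math.log(config.time_mean_at_200) - math.log(config.time_mean_start)
        ) / 199.0
        decline_cap = math.log(config.time_mean_at_200) - math.log(config.time_mean_start)
        c = 0.0
        tcar = 0.0
        for j, L in enumerate(lengths):
            if j > 0:
                frac = 1.0 - reset_fraction_for_break(config, float(breaks[j]))
                c *= frac
                tcar *= frac
            carry[j] = c
            time_carry[j] = tcar
            c += config.criterion_drift_per_case * L
            tcar = max(decline_cap, tcar + decline_rate * L)

        woman_idx = np.concatenate([m[0] for m in order_parts])
        moved_mask = np.concatenate([m[1] for m in order_parts])
        # intended order index follows the woman through reversal and moves
        intended_idx = np.concatenate(
            [
                _intended_indices(sessions[s], m[0])
                for (s, _, _), m in zip(sess_meta, order_parts)
            ]
        )
        pos = np.concatenate([np.arange(1, L + 1) for L in lengths])
        sess_of_event = np.repeat(np.arange(len(sess_meta)), lengths)

        crit = (
            config.criterion_base
            + profile.criterion_intercept_deviation
            + carry[sess_of_event]
            + config.criterion_drift_per_case * (pos - 1)
            + config.woman_position_effect * (intended_idx - 1)
        )
        signal = is_signal[woman_idx]
        p_recall = np.where(
            signal,
            norm.cdf(profile.d_prime / 2.0 - crit),
            norm.cdf(-profile.d_prime / 2.0 - crit),
        )
        recall = rng.random(n_ev) < p_recall

        decline = np.maximum(
            decline_cap, time_carry[sess_of_event] + decline_rate * (pos - 1)
        )
        mean_t = np.exp(
            math.log(config.time_mean_start)
            + decline
            + profile.log_time_intercept_deviation
        )
        mean_t = mean_t + np.where(recall, config.recall_time_offset_seconds, 0.0)
        # floor at 0.1 s: a decision takes non-zero time, and timestamps must
        # stay strictly increasing at float resolution over long streams
        times = np.maximum(rng.gamma(shape, mean_t / shape), 0.1)
        gaps = times.copy()
        first_of_sess = np.r_[0, np.cumsum(lengths)[:-1]]
        gaps[first_of_sess[1:]] += breaks[1:] * 60.0
        timestamps = np.cumsum(gaps)

        sidx = np.array([m[0] for m in sess_meta])
        roles = np.array([m[1] for m in sess_meta])
        arm = session_arm[sidx][sess_of_event]
        role_ev = roles[sess_of_event]
        direction = np.where(
            (role_ev == "second") & (arm == "intervention"), "reverse", "forward"
        )
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": np.full(n_ev, profile.reader_id, dtype=np.int64),
                    "center_id": np.full(n_ev, profile.center_id, dtype=np.int64),
                    "woman_id": woman_idx.astype(np.int64),
                    "decision_timestamp": timestamps,
                    "decision": np.where(recall, "recall", "no_recall"),
                    "intended_order_index": intended_idx.astype(np.int64),
                    "arm": arm,
                    "direction": direction,
                    "reader_role": role_ev,
                    "moved": moved_mask,
                }
            )
        )

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["reader_id", "decision_timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    return women, events


def _intended_indices(original: np.ndarray, reading_order: np.ndarray) -> np.ndarray:
    """Intended (list) 1-based index of each woman in reading order."""
    lookup = {int(w): i + 1 for i, w in enumerate(original)}
    return np.fromiter((lookup[int(w)] for w in reading_order), dtype=np.int64)


# ---------------------------------------------------------------------------
# Direct mixed-model generator (for parameter-recovery studies)
# ---------------------------------------------------------------------------


def simulate_records_glmm(
    n_records: int,
    coefficients: dict[str, float],
    family: Literal["binomial", "gamma"],
    *,
    n_readers: int = 50,
    n_centers: int = 10,
    sigma_reader: float = 0.2,
    sigma_center: float = 0.1,
    gamma_shape: float = 2.0,
    interior_knots: tuple[float, ...] = (20.0, 40.0),
    boundary: tuple[float, float] = (2.0, 200.0),
    position_term: Literal["spline", "linear"] = "spline",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw analysis-ready records from a known multilevel GLM.

    Positions are sampled with the declining density induced by lognormal
    session lengths (median 35), ages from the screening range, and the
    outcome from a logistic (binomial) or log-link gamma model with nested
    reader-within-center random intercepts of the given SDs.  Returns the
    records and the ground-truth parameter dictionary, for checking that
    the fitting code recovers what generated the data.

    ``coefficients`` keys follow the fitted design: ``intercept``,
    ``spline_1``..``spline_3`` (or ``position`` for the linear term),
    ``age_c`` (age centred at 59, per year) and ``first_screen``.
    """
    from .models import SplineBasis, design_matrix

    rng = np.random.default_rng(seed)
    reader = rng.integers(0, n_readers, size=n_records)
    center = reader % n_centers
    u = sigma_reader * rng.standard_normal(n_readers)
    v = sigma_center * rng.standard_normal(n_centers)

    lo, hi = boundary
    grid = np.arange(int(lo), int(hi) + 1)
    surv = 1.0 - norm.cdf((np.log(grid) - math.log(35.0)) / 0.6)
    weights = surv / surv.sum()
    position = rng.choice(grid, size=n_records, p=weights)
    age = np.clip(rng.normal(59.0, 5.5, size=n_records), 47.0, 73.0)
    first_screen = rng.random(n_records) < 0.21

    df = pd.DataFrame(
        {
            "reader_id": reader,
            "center_id": center,
            "position": position,
            "age": age,
            "first_screen": first_screen,
        }
    )
    basis = SplineBasis(interior_knots=interior_knots, boundary=boundary)
    X, names = design_matrix(df, basis, position_term=position_term)
    beta = np.array([coefficients[n] for n in names])
    eta = X @ beta + u[reader] + v[center]
    if family == "binomial":
        df["y"] = (rng.random(n_records) < special.expit(eta)).astype(int)
    elif family == "gamma":
        mu = np.exp(eta)
        df["y"] = rng.gamma(gamma_shape, mu / gamma_shape)
    else:
        raise ValueError(f"unknown family {family!r}")
    truth = dict(coefficients)
    truth.update(
        sigma_reader=sigma_reader, sigma_center=sigma_center, gamma_shape=gamma_shape
    )
    return df, truth
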