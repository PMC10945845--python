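"""Signal-detection closed forms shared by the simulator and the metrics layer.

The equal-variance Gaussian model: a reader observes evidence drawn from
N(+d'/2, 1) on cancer cases and N(-d'/2, 1) on normal cases, and recalls
whenever evidence exceeds the decision criterion.  Discriminability d' and
criterion c are recovered from a hit rate H (sensitivity) and false-alarm
rate F (1 - specificity) by

    d' = z(H) - z(F)
    c  = -0.5 * [z(H) + z(F)]

with z the standard-normal quantile function.  c > 0 means a conservative
reader (reluctant to recall); c = 0 is the unbiased point.
"""

from __future__ import annotations

from scipy.stats import norm

__all__ = [
    "d_prime",
    "criterion_c",
    "hit_false_alarm_rates",
    "correct_extreme_rates",
]


def _check_open_unit(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(
            f"{name}={value!r} must lie strictly inside (0, 1); rates of exactly "
            "0 or 1 must first be corrected, e.g. with correct_extreme_rates() "
            "which replaces 0 with 1/(2N) and 1 with 1 - 1/(2N)."
        )


def d_prime(sensitivity: float, specificity: float) -> float:
    """Discriminability index d' = z(sensitivity) - z(1 - specificity)."""
    _check_open_unit("sensitivity", sensitivity)
    _check_open_unit("specificity", specificity)
    return float(norm.ppf(sensitivity) - norm.ppf(1.0 - specificity))


def criterion_c(sensitivity: float, specificity: float) -> float:
    """Decision criterion c = -0.5 * [z(sensitivity) + z(1 - specificity)]."""
    _check_open_unit("sensitivity", sensitivity)
    _check_open_unit("specificity", specificity)
    return float(-0.5 * (norm.ppf(sensitivity) + norm.ppf(1.0 - specificity)))


def hit_false_alarm_rates(d_prime: float, criterion: float) -> tuple[float, float]:
    """Invert (d', c) back to (hit rate, false-alarm rate).

    Under the equal-variance model the hit rate is Phi(d'/2 - c) and the
    false-alarm rate Phi(-d'/2 - c).  Round-trips with :func:`d_prime` /
    :func:`criterion_c` to floating-point accuracy.
    """
    if d_prime < 0:
        raise ValueError(f"d_prime must be >= 0, got {d_prime!r}")
    hit = float(norm.cdf(d_prime / 2.0 - criterion))
    fa = float(norm.cdf(-d_prime / 2.0 - criterion))
    return hit, fa


def correct_extreme_rates(successes: int, n: int) -> float:
    """Proportion with the standard extreme-rate correction for SDT.

    Observed rates of exactly 0 or 1 make z() infinite; the conventional fix
    replaces a count of 0 with 1/2 and a count of n with n - 1/2, i.e. rates
    1/(2n) and 1 - 1/(2n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if successes == 0:
        return 1.0 / (2.0 * n)
    if successes == n:
        return 1.0 - 1.0 / (2.0 * n)
    return successes / n
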