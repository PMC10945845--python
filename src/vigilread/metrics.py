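"""Test-accuracy and signal-detection metrics by position in session.

Outcomes are classified against a 3-year reference standard: a woman "has
cancer" if it was detected at screening or diagnosed symptomatically within
3 years (an interval cancer).  Recall + cancer = TP, recall + no cancer =
FP, no recall + cancer = FN, no recall + no cancer = TN.  From the
confusion counts: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), with Wilson score intervals; d' and
criterion per the equal-variance model with Wald intervals from the
Gourevitch-Galanter variance approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .sdt import correct_extreme_rates, criterion_c, d_prime
from .sessions import position_bin_array

__all__ = [
    "ConfusionCounts",
    "RateEstimate",
    "SDTSummary",
    "classify_outcome",
    "classify_outcomes",
    "confusion_counts",
    "wilson_interval",
    "accuracy_summary",
    "sdt_summary",
    "rates_by_position",
    "sdt_by_bin",
    "accuracy_by_bin",
    "projected_excess_recalls",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_cancer(self) -> int:
        return self.tp + self.fn

    @property
    def n_normal(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with its Wilson confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0:
            raise ValueError("interval must satisfy 0 <= low <= value <= high <= 1")


@dataclass(frozen=True)
class SDTSummary:
    d_prime: float
    criterion: float
    d_prime_ci: tuple[float, float]
    criterion_ci: tuple[float, float]


def classify_outcome(decision: str, cancer_status: str) -> str:
    """Screening test outcome of one reading against the reference standard."""
    if decision not in ("recall", "no_recall"):
        raise ValueError(f"unknown decision {decision!r}")
    if cancer_status not in ("screen_detectable", "interval", "none"):
        raise ValueError(f"unknown cancer_status {cancer_status!r}")
    cancer = cancer_status != "none"
    if decision == "recall":
        return "TP" if cancer else "FP"
    return "FN" if cancer else "TN"


def classify_outcomes(records: pd.DataFrame) -> pd.Series:
    """Vectorised outcome classification for a records table."""
    recall = (records["decision"] == "recall").to_numpy()
    cancer = (records["cancer_status"] != "none").to_numpy()
    out = np.where(recall, np.where(cancer, "TP", "FP"), np.where(cancer, "FN", "TN"))
    return pd.Series(out, index=records.index, name="outcome")


def confusion_counts(records: pd.DataFrame) -> ConfusionCounts:
    oc = classify_outcomes(records)
    c = oc.value_counts()
    return ConfusionCounts(
        tp=int(c.get("TP", 0)),
        fp=int(c.get("FP", 0)),
        tn=int(c.get("TN", 0)),
        fn=int(c.get("FN", 0)),
    )


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


def _rate(successes: int, n: int, level: float) -> RateEstimate:
    lo, hi = wilson_interval(successes, n, level)
    value = successes / n
    # guard against floating-point overshoot at the boundaries
    lo = min(max(lo, 0.0), value)
    hi = max(min(hi, 1.0), value)
    return RateEstimate(value=value, ci_low=lo, ci_high=hi, n=n)


def accuracy_summary(
    counts: ConfusionCounts, level: float = 0.95
) -> dict[str, RateEstimate | None]:
    """Sensitivity, specificity, PPV and NPV with Wilson intervals.

    A metric whose denominator is zero is reported as None (undefined)
    rather than fabricated.
    """
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    return {
        name: (_rate(k, n, level) if n > 0 else None) for name, (k, n) in pairs.items()
    }


def sdt_summary(counts: ConfusionCounts, level: float = 0.95) -> SDTSummary:
    """d' and criterion with Wald CIs (Gourevitch-Galanter variance).

    Hit rate H = corrected sensitivity, false-alarm rate F = corrected
    1 - specificity.  var(d') = H(1-H)/(nS phi(z(H))^2) +
    F(1-F)/(nN phi(z(F))^2); the criterion, a half-sum of the same two
    quantiles, gets a quarter of that variance by the delta method.
    """
    n_s, n_n = counts.n_cancer, counts.n_normal
    if n_s <= 0 or n_n <= 0:
        raise ValueError("need at least one cancer and one normal trial")
    hit = correct_extreme_rates(counts.tp, n_s)
    fa = correct_extreme_rates(counts.fp, n_n)
    dp = d_prime(hit, 1.0 - fa)
    c = criterion_c(hit, 1.0 - fa)
    var_sum = hit * (1 - hit) / (n_s * norm.pdf(norm.ppf(hit)) ** 2) + fa * (
        1 - fa
    ) / (n_n * norm.pdf(norm.ppf(fa)) ** 2)
    z = norm.ppf(0.5 + level / 2.0)
    se_d = math.sqrt(var_sum)
    se_c = 0.5 * se_d
    return SDTSummary(
        d_prime=dp,
        criterion=c,
        d_prime_ci=(dp - z * se_d, dp + z * se_d),
        criterion_ci=(c - z * se_c, c + z * se_c),
    )


def rates_by_position(records: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Recall rate and cancer detection rate per position in session.

    Expects positioned records with exclusions applied (positions 2..200,
    first reader only).  Returns one tidy row per (position, metric) with
    value, Wilson ci_low/ci_high and n.  The cancer detection rate is the
    proportion of all women examined at that position who were correctly
    recalled with cancer (TP per woman screened).
    """
    recall = (records["decision"] == "recall").astype(int)
    tp = (recall.astype(bool) & (records["cancer_status"] != "none")).astype(int)
    g = pd.DataFrame(
        {"position": records["position"], "recall": recall, "tp": tp}
    ).groupby("position")
    agg = g.agg(n=("recall", "size"), recalls=("recall", "sum"), tps=("tp", "sum"))
    rows = []
    for pos, row in agg.iterrows():
        for metric, k in (("recall_rate", row["recalls"]), ("cancer_detection_rate", row["tps"])):
            lo, hi = wilson_interval(int(k), int(row["n"]), level)
            rows.append(
                {
                    "position": int(pos),
                    "metric": metric,
                    "value": k / row["n"],
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": int(row["n"]),
                }
            )
    return pd.DataFrame(rows)


def _bin_counts(records: pd.DataFrame) -> dict[int, ConfusionCounts]:
    bins = position_bin_array(records["position"].to_numpy())
    out = {}
    for b in sorted(np.unique(bins)):
        out[int(b)] = confusion_counts(records[bins == b])
    return out


def accuracy_by_bin(records: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV per position bin (tidy rows)."""
    rows = []
    for b, counts in _bin_counts(records).items():
        for name, est in accuracy_summary(counts, level).items():
            rows.append(
                {
                    "position_bin": b,
                    "metric": name,
                    "value": est.value if est else np.nan,
                    "ci_low": est.ci_low if est else np.nan,
                    "ci_high": est.ci_high if est else np.nan,
                    "n": est.n if est else 0,
                }
            )
    return pd.DataFrame(rows)


def sdt_by_bin(records: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """d' and criterion per position bin (tidy rows)."""
    rows = []
    for b, counts in _bin_counts(records).items():
        s = sdt_summary(counts, level)
        rows.append(
            {
                "position_bin": b,
                "metric": "d_prime",
                "value": s.d_prime,
                "ci_low": s.d_prime_ci[0],
                "ci_high": s.d_prime_ci[1],
                "n": counts.total,
            }
        )
        rows.append(
            {
                "position_bin": b,
                "metric": "criterion",
                "value": s.criterion,
                "ci_low": s.criterion_ci[0],
                "ci_high": s.criterion_ci[1],
                "n": counts.total,
            }
        )
    return pd.DataFrame(rows)


def projected_excess_recalls(
    rate_start: float, rate_end: float, annual_volume: int
) -> tuple[float, float]:
    """Programme-scale impact of the start-vs-end recall-rate difference.

    Returns (absolute excess recalls per year, percent relative to the
    end-of-session rate): e.g. recall rates of 4.66% at session start and
    3.24% at position 200 in a programme screening 2 million women/year
    correspond to 28,400 excess false-positive recalls, a 44% relative
    increase.
    """
    if not (0.0 <= rate_start <= 1.0 and 0.0 <= rate_end <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    absolute = annual_volume * (rate_start - rate_end)
    if rate_end == 0:
        raise ZeroDivisionError("relative excess undefined when rate_end is 0")
    relative = 100.0 * absolute / (annual_volume * rate_end)
    return absolute, relative
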