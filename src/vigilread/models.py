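"""The three multilevel models of reading behaviour.

Recall (logistic), cancer detection (logistic) and reading time (gamma,
log link) are modelled as functions of position in session with woman-level
covariates (age centred at 59, first-screen indicator) and nested random
intercepts for reader within screening centre.  Position enters recall and
time as a degree-1 (piecewise linear) B-spline with interior knots at
positions 20 and 40 over the analysis range 2..200 — the early part of a
session is where the curves bend — and as a plain linear term for cancer
detection, whose pattern is not curved.  The detection model reports its
position effect as an odds ratio per 5 additional cases since the last
break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .glmm import GLMMFit, fit_nested_glmm

__all__ = [
    "SplineBasis",
    "ModelSpec",
    "MixedFit",
    "linear_bspline_design",
    "design_matrix",
    "fit_recall_model",
    "fit_detection_model",
    "fit_time_model",
    "predict_curve",
]

REFERENCE_AGE = 59.0


@dataclass(frozen=True)
class SplineBasis:
    """Degree-1 B-spline basis over the position range."""

    interior_knots: tuple[float, ...] = (20.0, 40.0)
    boundary: tuple[float, float] = (2.0, 200.0)
    degree: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        knots = list(self.interior_knots)
        if knots != sorted(knots) or len(set(knots)) != len(knots):
            raise ValueError("interior knots must be strictly increasing")
        if knots and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if self.degree != 1:
            raise ValueError("only degree-1 (piecewise linear) bases are supported")

    @property
    def full_knots(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[lo, lo, list(self.interior_knots), hi, hi]

    @property
    def n_functions(self) -> int:
        return len(self.interior_knots) + 2


def linear_bspline_design(positions, basis: SplineBasis) -> np.ndarray:
    """Full degree-1 B-spline basis matrix (one hat function per column).

    The columns form a partition of unity, so a model with an intercept
    uses the basis with the first column dropped.
    """
    x = np.asarray(positions, dtype=float)
    lo, hi = basis.boundary
    if np.any((x < lo) | (x > hi)):
        raise ValueError(f"positions outside the basis boundary [{lo}, {hi}]")
    M = BSpline.design_matrix(x, basis.full_knots, basis.degree, extrapolate=False)
    return np.asarray(M.todense())


@dataclass(frozen=True)
class ModelSpec:
    """What to model and how position enters."""

    outcome: Literal["recall", "cancer_detected", "reading_time"]
    family: Literal["binomial", "gamma"]
    position_term: Literal["spline", "linear"]
    basis: SplineBasis = field(default_factory=SplineBasis)
    covariates: tuple[str, ...] = ("age", "first_screen")

    def __post_init__(self) -> None:
        if self.outcome == "cancer_detected" and self.position_term != "linear":
            raise ValueError("the cancer-detection model uses a linear position term")
        if self.outcome in ("recall", "cancer_detected") and self.family != "binomial":
            raise ValueError(f"{self.outcome} is a binary outcome (binomial family)")
        if self.outcome == "reading_time" and self.family != "gamma":
            raise ValueError("reading_time uses the gamma family")


def default_spec(outcome: str) -> ModelSpec:
    if outcome == "recall":
        return ModelSpec("recall", "binomial", "spline")
    if outcome == "cancer_detected":
        return ModelSpec("cancer_detected", "binomial", "linear")
    if outcome == "reading_time":
        return ModelSpec("reading_time", "gamma", "spline")
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclass
class MixedFit:
    """Fixed effects, variance components and metadata of a fitted model."""

    spec: ModelSpec
    glmm: GLMMFit
    position_range: tuple[float, float]

    @property
    def names(self) -> list[str]:
        return self.glmm.names

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.glmm.coef, "se": self.glmm.se}, index=self.glmm.names
        )

    @property
    def variance_components(self) -> dict[str, float]:
        return self.glmm.variance_components

    @property
    def log_likelihood(self) -> float:
        return self.glmm.log_likelihood

    @property
    def converged(self) -> bool:
        return self.glmm.converged

    def to_dict(self) -> dict:
        d = self.glmm.summary_dict()
        d["outcome"] = self.spec.outcome
        d["position_term"] = self.spec.position_term
        return d


def design_matrix(
    records: pd.DataFrame,
    basis: SplineBasis,
    position_term: Literal["spline", "linear"] = "spline",
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, position term, age (centred), first screen."""
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    if position_term == "spline":
        B = linear_bspline_design(records["position"].to_numpy(), basis)
        # drop the first hat function: with the intercept the rest span the space
        for j in range(1, B.shape[1]):
            cols.append(B[:, j])
            names.append(f"spline_{j}")
    elif position_term == "linear":
        cols.append(records["position"].to_numpy(dtype=float))
        names.append("position")
    else:
        raise ValueError(f"unknown position_term {position_term!r}")
    cols.append(records["age"].to_numpy(dtype=float) - REFERENCE_AGE)
    names.append("age_c")
    cols.append(records["first_screen"].to_numpy(dtype=float))
    names.append("first_screen")
    return np.column_stack(cols), names


def _check_grouping(records: pd.DataFrame) -> None:
    if records["reader_id"].nunique() < 2 or records["center_id"].nunique() < 2:
        raise ValueError("need at least 2 readers and 2 centers to fit the multilevel model")


def _fit(
    records: pd.DataFrame,
    spec: ModelSpec,
    y: np.ndarray,
    fixed_sigmas: tuple[float, float] | None,
) -> MixedFit:
    _check_grouping(records)
    X, names = design_matrix(records, spec.basis, spec.position_term)
    glmm = fit_nested_glmm(
        X,
        y,
        records["reader_id"].to_numpy(),
        records["center_id"].to_numpy(),
        family=spec.family,
        names=names,
        fixed_sigmas=fixed_sigmas,
    )
    pos = records["position"].to_numpy()
    return MixedFit(spec=spec, glmm=glmm, position_range=(float(pos.min()), float(pos.max())))


def fit_recall_model(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    fixed_sigmas: tuple[float, float] | None = None,
) -> MixedFit:
    """Multilevel logistic model of the recall decision with spline(position)."""
    spec = spec or default_spec("recall")
    y = (records["decision"] == "recall").to_numpy(dtype=float)
    return _fit(records, spec, y, fixed_sigmas)


def fit_detection_model(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    fixed_sigmas: tuple[float, float] | None = None,
    level: float = 0.95,
) -> MixedFit:
    """Multilevel logistic model of cancer detection, linear in position.

    Detection = the reader recalled a woman who has cancer (a true
    positive).  The fit reports ``or_per_5_cases`` = exp(5 * beta_position)
    with its Wald interval.
    """
    spec = spec or default_spec("cancer_detected")
    y = (
        (records["decision"] == "recall") & (records["cancer_status"] != "none")
    ).to_numpy(dtype=float)
    fit = _fit(records, spec, y, fixed_sigmas)
    j = fit.names.index("position")
    b, s = fit.glmm.coef[j], fit.glmm.se[j]
    z = norm.ppf(0.5 + level / 2.0)
    fit.glmm.extra["or_per_5_cases"] = float(np.exp(5.0 * b))
    fit.glmm.extra["or_per_5_cases_ci"] = (
        float(np.exp(5.0 * (b - z * s))),
        float(np.exp(5.0 * (b + z * s))),
    )
    return fit


def fit_time_model(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    fixed_sigmas: tuple[float, float] | None = None,
) -> MixedFit:
    """Multilevel gamma (log link) model of per-case reading time.

    Expects time-model exclusions already applied (0 < time <= 600 s).
    """
    spec = spec or default_spec("reading_time")
    y = records["reading_time_seconds"].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError(
            "reading times must be positive and finite; apply the time-model exclusions first"
        )
    return _fit(records, spec, y, fixed_sigmas)


def predict_curve(
    fit: MixedFit,
    positions,
    reference_covariates: dict | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Population-level fitted curve with delta-method confidence bands.

    The curve is conditional on random effects = 0, with covariates held
    at reference values (age 59, subsequent screen unless overridden).
    Bands are computed on the linear predictor from the fixed-effect
    covariance and transformed to the response scale, so they respect the
    outcome's range.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    positions = np.asarray(positions, dtype=float)
    lo, hi = fit.position_range
    if np.any((positions < lo) | (positions > hi)):
        raise ValueError(f"positions outside the fitted range [{lo}, {hi}]")
    ref = {"age": REFERENCE_AGE, "first_screen": False}
    ref.update(reference_covariates or {})
    frame = pd.DataFrame(
        {
            "position": positions,
            "age": np.full(len(positions), float(ref["age"])),
            "first_screen": np.full(len(positions), bool(ref["first_screen"])),
        }
    )
    X, _ = design_matrix(frame, fit.spec.basis, fit.spec.position_term)
    eta = X @ fit.glmm.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.glmm.cov, X))
    z = norm.ppf(0.5 + level / 2.0)
    link_inv = (lambda e: 1.0 / (1.0 + np.exp(-e))) if fit.spec.family == "binomial" else np.exp
    return pd.DataFrame(
        {
            "position": positions,
            "fitted": link_inv(eta),
            "ci_low": link_inv(eta - z * se),
            "ci_high": link_inv(eta + z * se),
        }
    )
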