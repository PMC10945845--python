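"""Generalized linear mixed models with nested random intercepts.

Fits logistic (binomial) and log-link gamma models of the form

    g(E[y_i]) = x_i' beta + u_reader(i) + v_center(i),
    u_r ~ N(0, sigma_u^2),  v_c ~ N(0, sigma_v^2)

by maximizing the Laplace approximation to the marginal likelihood.  For a
candidate pair of variance components, penalized iteratively reweighted
least squares (Fisher scoring with step halving) locates the joint mode of
(beta, u, v); the fixed effects are profiled out at that mode, and the
Laplace log-likelihood is the penalized log-likelihood at the mode minus
half the log-determinant of the random-effects block of the (weighted)
information matrix.  The two variance components are then optimized on the
log-SD scale with Nelder-Mead, warm-starting the mode between evaluations.
The gamma shape (inverse dispersion) is profiled via the Pearson estimator
at each mode.

Standard errors for the fixed effects come from the fixed-effect block of
the inverse of the full joint information matrix at the optimum, i.e. Wald
intervals conditional on the estimated variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = ["GLMMFit", "fit_nested_glmm"]

_MIN_LOG_SIGMA = math.log(1e-4)


@dataclass
class GLMMFit:
    """Result of a nested-random-intercept GLMM fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    variance_components: dict[str, float]
    log_likelihood: float
    converged: bool
    family: str
    n_obs: int
    random_effects: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    extra: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "family": self.family,
            "n_obs": self.n_obs,
            "coefficients": {
                n: {"estimate": float(b), "se": float(s)}
                for n, b, s in zip(self.names, self.coef, self.se)
            },
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            **{k: v for k, v in self.extra.items() if np.isscalar(v)},
        }


def _family_funcs(family: str):
    """score(eta, y) wrt eta, Fisher weight(eta, y), loglik(eta, y, aux)."""
    if family == "binomial":

        def loglik(eta, y, aux):
            # log f = y*eta - log(1 + e^eta), stable via logaddexp
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        def score(eta, y, aux):
            return y - special.expit(eta)

        def weight(eta, y, aux):
            mu = special.expit(eta)
            return mu * (1.0 - mu)

    elif family == "gamma":
        # aux = shape nu; log link: mu = e^eta
        def loglik(eta, y, aux):
            nu = aux
            return float(
                np.sum(
                    nu * (math.log(nu) - eta)
                    + (nu - 1.0) * np.log(y)
                    - nu * y * np.exp(-eta)
                )
                - len(y) * special.gammaln(nu)
            )

        def score(eta, y, aux):
            return aux * (y * np.exp(-eta) - 1.0)

        def weight(eta, y, aux):
            return np.full(len(y), aux)

    else:
        raise ValueError(f"unknown family {family!r}")
    return loglik, score, weight


def _pirls(
    X, y, reader, center, R, C, sig_u, sig_v, family, aux, state, max_iter=60, tol=1e-7
):
    """Joint mode of (beta, u, v) at fixed variance components.

    Returns (beta, u, v, eta, w, penalized loglik, converged).
    """
    loglik, score_f, weight_f = _family_funcs(family)
    n, p = X.shape
    use_u = sig_u > 0
    use_v = sig_v > 0
    beta = state["beta"].copy()
    u = state["u"].copy() if use_u else np.zeros(R)
    v = state["v"].copy() if use_v else np.zeros(C)
    inv_u = 1.0 / sig_u**2 if use_u else 0.0
    inv_v = 1.0 / sig_v**2 if use_v else 0.0

    def eta_of(beta, u, v):
        e = X @ beta
        if use_u:
            e = e + u[reader]
        if use_v:
            e = e + v[center]
        return e

    def pen_ll(beta, u, v, eta):
        pen = 0.0
        if use_u:
            pen += 0.5 * inv_u * float(u @ u)
        if use_v:
            pen += 0.5 * inv_v * float(v @ v)
        return loglik(eta, y, aux) - pen

    eta = eta_of(beta, u, v)
    current = pen_ll(beta, u, v, eta)
    converged = False
    rc = reader * C + center
    for _ in range(max_iter):
        s = score_f(eta, y, aux)
        w = weight_f(eta, y, aux)
        # gradient
        g_parts = [X.T @ s]
        if use_u:
            g_parts.append(np.bincount(reader, weights=s, minlength=R) - inv_u * u)
        if use_v:
            g_parts.append(np.bincount(center, weights=s, minlength=C) - inv_v * v)
        grad = np.concatenate(g_parts)
        # Fisher information (dense; p + R + C is small)
        Xw = X * w[:, None]
        H_bb = X.T @ Xw
        blocks = [H_bb]
        dim = p + (R if use_u else 0) + (C if use_v else 0)
        H = np.zeros((dim, dim))
        H[:p, :p] = H_bb
        off = p
        if use_u:
            XWu = np.stack(
                [np.bincount(reader, weights=Xw[:, j], minlength=R) for j in range(p)]
            )
            Du = np.bincount(reader, weights=w, minlength=R)
            H[:p, off : off + R] = XWu
            H[off : off + R, :p] = XWu.T
            H[off : off + R, off : off + R] = np.diag(Du + inv_u)
            off_u = off
            off += R
        if use_v:
            XWv = np.stack(
                [np.bincount(center, weights=Xw[:, j], minlength=C) for j in range(p)]
            )
            Dv = np.bincount(center, weights=w, minlength=C)
            H[:p, off : off + C] = XWv
            H[off : off + C, :p] = XWv.T
            H[off : off + C, off : off + C] = np.diag(Dv + inv_v)
            if use_u:
                Mrc = np.bincount(rc, weights=w, minlength=R * C).reshape(R, C)
                H[off_u : off_u + R, off : off + C] = Mrc
                H[off : off + C, off_u : off_u + R] = Mrc.T
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving on the penalized log-likelihood
        scale = 1.0
        for _ in range(30):
            nb = beta + scale * step[:p]
            nu_ = u + scale * step[p : p + R] if use_u else u
            nv_ = (
                v + scale * step[p + (R if use_u else 0) :] if use_v else v
            )
            neta = eta_of(nb, nu_, nv_)
            new = pen_ll(nb, nu_, nv_, neta)
            if new >= current - 1e-12:
                break
            scale *= 0.5
        improved = new - current
        beta, u, v, eta, current = nb, nu_, nv_, neta, new
        if abs(improved) < tol * (abs(current) + 1.0) and np.max(np.abs(grad)) < 1e-4 * n:
            converged = True
            break
    s = score_f(eta, y, aux)
    w = weight_f(eta, y, aux)
    state["beta"], state["u"], state["v"] = beta.copy(), u.copy(), v.copy()
    return beta, u, v, eta, w, current, converged


def _laplace_logdet(reader, center, R, C, w, sig_u, sig_v, rc):
    """log det of the random-effects information block Z'WZ + Sigma^-1."""
    use_u = sig_u > 0
    use_v = sig_v > 0
    if not use_u and not use_v:
        return 0.0, 0
    parts = []
    if use_u:
        Du = np.bincount(reader, weights=w, minlength=R) + 1.0 / sig_u**2
        parts.append(("u", Du))
    if use_v:
        Dv = np.bincount(center, weights=w, minlength=C) + 1.0 / sig_v**2
        parts.append(("v", Dv))
    if use_u and use_v:
        Mrc = np.bincount(rc, weights=w, minlength=R * C).reshape(R, C)
        q = R + C
        Hb = np.zeros((q, q))
        Hb[:R, :R] = np.diag(parts[0][1])
        Hb[R:, R:] = np.diag(parts[1][1])
        Hb[:R, R:] = Mrc
        Hb[R:, :R] = Mrc.T
        sign, logdet = np.linalg.slogdet(Hb)
        return float(logdet), q
    diag = parts[0][1]
    return float(np.sum(np.log(diag))), len(diag)


def fit_nested_glmm(
    X: np.ndarray,
    y: np.ndarray,
    reader_idx: np.ndarray,
    center_idx: np.ndarray,
    family: str = "binomial",
    names: list[str] | None = None,
    fixed_sigmas: tuple[float, float] | None = None,
    start_sigmas: tuple[float, float] = (0.3, 0.2),
    xatol: float = 0.02,
    fatol: float = 0.05,
) -> GLMMFit:
    """Fit the nested-random-intercept GLMM by Laplace approximation.

    ``fixed_sigmas`` pins the (reader, center) random-intercept SDs instead
    of estimating them; ``(0, 0)`` reduces the fit to an ordinary GLM on
    the pooled data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    reader, r_levels = _codes(reader_idx)
    center, c_levels = _codes(center_idx)
    R, C = len(r_levels), len(c_levels)
    n, p = X.shape
    if family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma outcomes must be strictly positive")
    loglik_f, _, _ = _family_funcs(family)
    rc = reader * C + center
    state = {"beta": np.zeros(p), "u": np.zeros(R), "v": np.zeros(C)}
    if family == "gamma":
        state["beta"][0] = math.log(max(float(np.mean(y)), 1e-12))
    aux_state = {"nu": 1.0}

    def objective(log_sigmas) -> float:
        sig_u = math.exp(max(log_sigmas[0], _MIN_LOG_SIGMA))
        sig_v = math.exp(max(log_sigmas[1], _MIN_LOG_SIGMA))
        if log_sigmas[0] <= _MIN_LOG_SIGMA:
            sig_u = 0.0
        if log_sigmas[1] <= _MIN_LOG_SIGMA:
            sig_v = 0.0
        aux = aux_state["nu"] if family == "gamma" else None
        for _ in range(2 if family == "gamma" else 1):
            beta, u, v, eta, w, pll, _ = _pirls(
                X, y, reader, center, R, C, sig_u, sig_v, family, aux, state
            )
            if family == "gamma":
                mu = np.exp(eta)
                pearson = float(np.sum(((y - mu) / mu) ** 2))
                aux = max((n - p) / max(pearson, 1e-12), 1e-3)
            else:
                break
        if family == "gamma":
            aux_state["nu"] = aux
            pll = _penalized_ll(loglik_f, eta, y, aux, u, v, sig_u, sig_v)
        logdet, q = _laplace_logdet(reader, center, R, C, w, sig_u, sig_v, rc)
        ll = pll - 0.5 * logdet
        if sig_u > 0:
            ll -= R * math.log(sig_u)
        if sig_v > 0:
            ll -= C * math.log(sig_v)
        return -ll

    if fixed_sigmas is not None:
        sig_u, sig_v = fixed_sigmas
        log_s = [
            math.log(sig_u) if sig_u > 0 else _MIN_LOG_SIGMA - 1,
            math.log(sig_v) if sig_v > 0 else _MIN_LOG_SIGMA - 1,
        ]
        neg_ll = objective(log_s)
        outer_ok = True
    else:
        x0 = np.log(np.asarray(start_sigmas, dtype=float))
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": 200},
        )
        log_s = res.x
        neg_ll = objective(log_s)  # re-evaluate to leave state at the optimum
        sig_u = math.exp(log_s[0]) if log_s[0] > _MIN_LOG_SIGMA else 0.0
        sig_v = math.exp(log_s[1]) if log_s[1] > _MIN_LOG_SIGMA else 0.0
        outer_ok = bool(res.success) or res.status == 2  # maxfev hit still usable

    aux = aux_state["nu"] if family == "gamma" else None
    beta, u, v, eta, w, pll, inner_ok = _pirls(
        X, y, reader, center, R, C, sig_u, sig_v, family, aux, state
    )
    cov = _fixed_effect_cov(X, w, reader, center, R, C, sig_u, sig_v, rc, p)
    se = np.sqrt(np.diag(cov))
    fit = GLMMFit(
        names=names or [f"x{j}" for j in range(p)],
        coef=beta,
        se=se,
        cov=cov,
        variance_components={"reader": sig_u**2, "center": sig_v**2},
        log_likelihood=-neg_ll,
        converged=bool(inner_ok and outer_ok),
        family=family,
        n_obs=n,
        random_effects={"reader": u, "center": v},
    )
    if family == "gamma":
        fit.extra["gamma_shape"] = float(aux_state["nu"])
    return fit


def _penalized_ll(loglik_f, eta, y, aux, u, v, sig_u, sig_v):
    pll = loglik_f(eta, y, aux)
    if sig_u > 0:
        pll -= 0.5 * float(u @ u) / sig_u**2
    if sig_v > 0:
        pll -= 0.5 * float(v @ v) / sig_v**2
    return pll


def _fixed_effect_cov(X, w, reader, center, R, C, sig_u, sig_v, rc, p):
    """Fixed-effect block of the inverse joint information matrix."""
    use_u = sig_u > 0
    use_v = sig_v > 0
    Xw = X * w[:, None]
    dim = p + (R if use_u else 0) + (C if use_v else 0)
    H = np.zeros((dim, dim))
    H[:p, :p] = X.T @ Xw
    off = p
    if use_u:
        XWu = np.stack([np.bincount(reader, weights=Xw[:, j], minlength=R) for j in range(p)])
        H[:p, off : off + R] = XWu
        H[off : off + R, :p] = XWu.T
        H[off : off + R, off : off + R] = np.diag(
            np.bincount(reader, weights=w, minlength=R) + 1.0 / sig_u**2
        )
        off_u = off
        off += R
    if use_v:
        XWv = np.stack([np.bincount(center, weights=Xw[:, j], minlength=C) for j in range(p)])
        H[:p, off : off + C] = XWv
        H[off : off + C, :p] = XWv.T
        H[off : off + C, off : off + C] = np.diag(
            np.bincount(center, weights=w, minlength=C) + 1.0 / sig_v**2
        )
        if use_u:
            Mrc = np.bincount(rc, weights=w, minlength=R * C).reshape(R, C)
            H[off_u : off_u + R, off : off + C] = Mrc
            H[off : off + C, off_u : off_u + R] = Mrc.T
    Hinv = np.linalg.inv(H)
    return Hinv[:p, :p]


def _codes(idx) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(np.asarray(idx), return_inverse=True)
    return codes.astype(np.int64), levels
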