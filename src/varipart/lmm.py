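"""Per-gene linear mixed model fitting.

The model for one gene's expression vector ``y`` (length n) is

    y = sum_j X_j b_j + sum_k Z_k a_k + e,
    a_k ~ N(0, s2_k I),   e ~ N(0, s2_e R),

with one variance component per random term and an optional heteroskedastic
residual: with per-sample precision weights ``w`` the residual covariance is
``diag(1/w) * s2_e`` (so high-precision samples get small residual variance).

Estimation profiles out the fixed effects and the residual variance and
optimises the variance *ratios* g_k = s2_k / s2_e on the log scale with an
analytic gradient (L-BFGS-B).  The log parameterisation keeps every
component non-negative; components whose share of the total falls below
1e-8 are reported as exactly 0.  Maximum likelihood is the default;
REML is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .design import DesignBundle

__all__ = ["FitResult", "IdentifiabilityError", "fit_lmm_ml", "fit_ols_anova"]

#: components smaller than this fraction of the total are snapped to zero
ZERO_TOL = 1e-8
#: relative log-likelihood convergence tolerance
REL_TOL = 1e-8
MAX_ITER = 500
_LOG_BOUND = 25.0  # bounds on log variance ratios


class IdentifiabilityError(ValueError):
    """Raised when a fixed-effects design is singular, so the variance
    decomposition is not identifiable."""


@dataclass
class FitResult:
    """Estimates from one per-gene fit.

    ``beta`` maps each fixed term to its coefficient vector (the intercept,
    when present, is stored separately); ``var_random`` holds one variance
    per random term, in squared expression units; ``var_resid`` is the
    residual variance parameter (for weighted fits, at unit precision).
    """

    method: str
    intercept: float
    beta: dict[str, np.ndarray]
    var_random: dict[str, float]
    var_resid: float
    loglik: float
    converged: bool
    n_iter: int
    message: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def random_terms(self) -> tuple[str, ...]:
        return tuple(self.var_random)


def _validate_y(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != n:
        raise ValueError(f"y has length {y.shape[0]}, design has {n} samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return y


def _prepare_weights(
    weights, n: int, convention: str
) -> np.ndarray | None:
    """Return per-sample residual variance multipliers (mean-1 normalised).

    With the default ``"precision"`` convention the supplied weights are
    inverse variances, so the residual covariance is diag(1/w)*s2_e; with
    ``"variance"`` they scale the residual variance directly.  Weights are
    normalised to geometric mean 1 so that their overall scale is absorbed
    into s2_e and constant weights reproduce the unweighted fit exactly.
    """
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != n:
        raise ValueError(f"weights have length {w.shape[0]}, expected {n}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    if convention == "precision":
        r = 1.0 / w
    elif convention == "variance":
        r = w.copy()
    else:
        raise ValueError(f"unknown weight convention {convention!r}")
    r /= np.exp(np.mean(np.log(r)))
    return r


def _profiled_nll_and_grad(theta, X, Zs, y, rdiag, n, p, reml):
    """-2 log-likelihood profiled over beta and s2_e, plus gradient in theta.

    theta are log variance ratios; rdiag is the per-sample residual variance
    multiplier (None = homoskedastic).
    """
    gam = np.exp(theta)
    V = np.diag(rdiag) if rdiag is not None else np.eye(n)
    for g, Z in zip(gam, Zs):
        V += g * (Z @ Z.T)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        # ill-conditioned V from an overshooting line-search step: report a
        # large objective so the optimizer backtracks
        return np.inf, np.zeros_like(theta), None, None, None, None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = cho_solve((c, low), r)
    q = float(r @ Vi_r)
    dof = n - p if reml else n
    nll = dof * np.log(q / dof) + logdet + dof * (1.0 + np.log(2.0 * np.pi))
    if reml:
        sign, ld2 = np.linalg.slogdet(XtViX)
        nll += ld2
        XtViX_inv = np.linalg.inv(XtViX)
    grad = np.empty_like(theta)
    for k, Z in enumerate(Zs):
        LiZ = solve_triangular(c, Z, lower=True)
        tr = float(np.sum(LiZ * LiZ))  # tr(V^-1 Z Z')
        u = Z.T @ Vi_r
        quad = float(u @ u)
        g = tr - dof * quad / q
        if reml:
            M = Vi_X.T @ Z  # X' V^-1 Z
            g -= float(np.sum((M @ M.T) * XtViX_inv))
        grad[k] = g * gam[k]
    return nll, grad, beta, q, c, low


def _ols_core(y, Xfull, n):
    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    resid = y - Xfull @ beta
    return beta, resid


def fit_lmm_ml(
    y,
    designs: DesignBundle,
    weights=None,
    method: str = "ML",
    weight_convention: str = "precision",
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Fit the mixed model for one gene and return variance components.

    Parameters
    ----------
    y
        Expression values for one gene, aligned to ``designs.sample_ids``.
    designs
        Output of :func:`varipart.design.build_design`.
    weights
        Optional per-sample precision weights (see ``weight_convention``).
    method
        ``"ML"`` (default) or ``"REML"``.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    n = designs.n_samples
    y = _validate_y(y, n)
    rdiag = _prepare_weights(weights, n, weight_convention)

    Xfull = designs.combined_fixed()
    p = Xfull.shape[1]
    if p >= n:
        raise ValueError(
            f"fixed-effect design has {p} columns for {n} samples; "
            f"offending terms: {list(designs.X)}"
        )
    if p and np.linalg.matrix_rank(Xfull) < p:
        raise IdentifiabilityError(
            "fixed-effect design is singular; the variance decomposition "
            "is not identifiable"
        )

    terms = list(designs.Z)
    Zs = [designs.Z[t] for t in terms]
    reml = method == "REML"

    if not terms:
        # pure fixed-effects model: closed form
        if rdiag is not None:
            sw = 1.0 / np.sqrt(rdiag)
            beta, _ = _ols_core(y * sw, Xfull * sw[:, None], n)
            resid = y - Xfull @ beta
            q = float(np.sum(resid**2 / rdiag))
            ldet = float(np.sum(np.log(rdiag)))
        else:
            beta, resid = _ols_core(y, Xfull, n)
            q = float(resid @ resid)
            ldet = 0.0
        dof = n - p if reml else n
        s2 = q / dof if q > 0 else 0.0
        ll = _gaussian_loglik(q, ldet, s2, n)
        return FitResult(
            method=method,
            intercept=float(beta[0]) if designs.intercept else 0.0,
            beta=_split_beta(beta, designs),
            var_random={},
            var_resid=s2,
            loglik=ll,
            converged=True,
            n_iter=0,
        )

    obj = lambda th: _profiled_nll_and_grad(th, Xfull, Zs, y, rdiag, n, p, reml)[:2]
    # the profiled objective can be flat near the zero-variance boundary, and
    # a long first line-search step may overshoot an interior basin; a few
    # deterministic starts on the variance-ratio scale make this robust
    res = None
    for g0 in (0.5, 0.05, 5.0):
        cand = minimize(
            obj,
            np.full(len(terms), np.log(g0)),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * len(terms),
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res is None or cand.fun < res.fun:
            res = cand
        if res.success and np.all(np.abs(res.x) < _LOG_BOUND - 1e-3):
            break
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5
    if not converged:
        warnings.warn(
            f"mixed-model fit did not converge ({res.message}); "
            "returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    nll, _, beta, q, c, low = _profiled_nll_and_grad(
        res.x, Xfull, Zs, y, rdiag, n, p, reml
    )
    dof = n - p if reml else n
    s2e = q / dof
    gam = np.exp(res.x)
    var_random = {t: float(g * s2e) for t, g in zip(terms, gam)}
    total = sum(var_random.values()) + s2e
    if total > 0:
        var_random = {
            t: (0.0 if v / total < ZERO_TOL else v) for t, v in var_random.items()
        }
    return FitResult(
        method=method,
        intercept=float(beta[0]) if designs.intercept else 0.0,
        beta=_split_beta(beta, designs),
        var_random=var_random,
        var_resid=float(s2e),
        loglik=-0.5 * float(nll),
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def _gaussian_loglik(q, ldet, s2, n):
    if s2 <= 0:
        return np.inf
    return -0.5 * (n * np.log(2 * np.pi * s2) + ldet + q / s2)


def _split_beta(beta: np.ndarray, designs: DesignBundle) -> dict[str, np.ndarray]:
    out = {}
    i = 1 if designs.intercept else 0
    for t, Xj in designs.X.items():
        out[t] = np.asarray(beta[i : i + Xj.shape[1]], dtype=float)
        i += Xj.shape[1]
    return out


def fit_ols_anova(y, designs: DesignBundle) -> FitResult:
    """Fixed-effects ANOVA comparator: every term fit as a fixed effect by
    ordinary least squares.

    Random terms from the model spec are re-coded as treatment-contrast fixed
    effects.  A rank-deficient combined design — e.g. when one factor is
    constant within the levels of another — raises
    :class:`IdentifiabilityError`, since the decomposition is then not
    identifiable.  The residual variance uses the maximum-likelihood
    denominator n, matching :func:`fit_lmm_ml` on fixed-effects-only specs.
    """
    n = designs.n_samples
    y = _validate_y(y, n)
    if designs.varying_parent:
        raise ValueError("the OLS/ANOVA comparator does not support varying terms")
    blocks = [np.ones((n, 1))] if designs.intercept else []
    slices: dict[str, slice] = {}
    i = 1 if designs.intercept else 0
    for t in list(designs.X) + list(designs.Z):
        B = designs.fixed_encoding(t)
        blocks.append(B)
        slices[t] = slice(i, i + B.shape[1])
        i += B.shape[1]
    Xfull = np.hstack(blocks)
    if Xfull.shape[1] >= n:
        raise ValueError(
            f"OLS design has {Xfull.shape[1]} columns for {n} samples"
        )
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise IdentifiabilityError(
            "the combined fixed-effects design matrix is degenerate "
            "(singular); the ANOVA variance decomposition is not identifiable"
        )
    beta, resid = _ols_core(y, Xfull, n)
    q = float(resid @ resid)
    s2 = q / n
    ll = _gaussian_loglik(q, 0.0, s2, n) if s2 > 0 else np.inf
    return FitResult(
        method="OLS",
        intercept=float(beta[0]) if designs.intercept else 0.0,
        beta={t: np.asarray(beta[sl], dtype=float) for t, sl in slices.items()},
        var_random={},
        var_resid=s2,
        loglik=ll,
        converged=True,
        n_iter=0,
    )
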