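"""Laplace-approximated binomial GLMM with crossed patch and year intercepts.

Model for one transition response (colonization or extinction):

    logit P(y_i = 1) = x_i' beta + u_year[t(i)] + u_patch[p(i)],
    u_year ~ N(0, sigma2_year I),  u_patch ~ N(0, sigma2_patch I).

Fitting maximises the Laplace approximation to the marginal likelihood.
For fixed variance components, the conditional mode of (beta, u) is found
by a penalised Newton iteration; the patch block of the Hessian is diagonal
(no two patches share an observation row), so each Newton step reduces to a
dense solve of dimension p + n_year after eliminating the patch block.
The variance components are then profiled by a derivative-free outer
optimisation on the log-sigma scale.

The same routine covers the plain logistic regression limit: a variance
component fixed at zero removes its random factor entirely, and with both
fixed at zero the reported log-likelihood is the exact binomial
log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised when the mixed-model optimisation fails to converge."""


class SeparationWarning(UserWarning):
    """Quasi-separated response; a weak ridge was applied to the slopes."""


@dataclass
class GLMMResult:
    beta: np.ndarray
    vcov: np.ndarray
    sigma2_patch: float
    sigma2_year: float
    u_patch: np.ndarray
    u_year: np.ndarray
    loglik: float
    n: int
    n_params_fixed: int
    n_params_var: int
    converged: bool
    gradient_norm: float
    ridge: float = 0.0
    patch_levels: np.ndarray = field(default=None)
    year_levels: np.ndarray = field(default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * (self.n_params_fixed + self.n_params_var)


def _inner_mode(y, X, patch, year, n_patch, n_year, s2p, s2y, ridge, theta0=None,
                max_iter=80, tol=1e-5):
    """Penalised Newton for the joint mode of (beta, u_year, u_patch).

    Returns the mode, the penalised objective, the Schur complement of the
    dense (beta, year) block, per-patch Hessian diagonal, cross block, and
    the converged flag.  ``theta0`` warm-starts the iteration.
    """
    n, p = X.shape
    use_y = s2y > 0
    use_p = s2p > 0
    if use_y:
        Zy = np.zeros((n, n_year))
        Zy[np.arange(n), year] = 1.0
        A = np.hstack([X, Zy])
    else:
        A = X
    ntop = A.shape[1]
    pen_top = np.zeros(ntop)
    pen_top[:p] = ridge
    if use_y:
        pen_top[p:] = 1.0 / s2y

    theta = np.zeros(ntop + (n_patch if use_p else 0)) if theta0 is None else theta0.copy()

    def objective(th):
        top, up = th[:ntop], th[ntop:]
        eta = A @ top + (up[patch] if use_p else 0.0)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        pen = 0.5 * float(np.sum(pen_top * top**2))
        if use_p:
            pen += 0.5 * float(np.sum(up**2)) / s2p
        return ll - pen

    f = objective(theta)
    S = dp = C = None
    gnorm = np.inf
    converged = False
    for _ in range(max_iter):
        top, up = theta[:ntop], theta[ntop:]
        eta = A @ top + (up[patch] if use_p else 0.0)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        resid = y - mu
        g_top = A.T @ resid - pen_top * top
        Aw = A * w[:, None]
        G = A.T @ Aw + np.diag(pen_top)
        if use_p:
            g_p = np.bincount(patch, weights=resid, minlength=n_patch) - up / s2p
            dp = np.bincount(patch, weights=w, minlength=n_patch) + 1.0 / s2p
            C = np.empty((ntop, n_patch))
            for k in range(ntop):
                C[k] = np.bincount(patch, weights=Aw[:, k], minlength=n_patch)
            S = G - (C / dp) @ C.T
            rhs = g_top - C @ (g_p / dp)
            gnorm = max(np.max(np.abs(g_top)), np.max(np.abs(g_p)))
        else:
            S = G
            rhs = g_top
            gnorm = np.max(np.abs(g_top))
        if gnorm < tol:
            converged = True
            break
        try:
            cf = linalg.cho_factor(S, lower=True)
            d_top = linalg.cho_solve(cf, rhs)
        except linalg.LinAlgError:
            d_top = np.linalg.lstsq(S, rhs, rcond=None)[0]
        if use_p:
            d_p = (g_p - C.T @ d_top) / dp
            step = np.concatenate([d_top, d_p])
        else:
            step = d_top
        # step halving keeps the penalised objective non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            fc = objective(cand)
            if fc >= f - 1e-12:
                theta, f = cand, fc
                break
            scale *= 0.5
        else:
            break
    return theta, f, S, dp, C, converged, gnorm, ntop


def _laplace_loglik(f_pen, S, dp, C, p, s2p, s2y, n_patch, n_year, use_p, use_y):
    """Marginal log-likelihood from the penalised objective at the mode.

    f_pen excludes the Gaussian normalising constants, which are added here
    together with the Laplace log-determinant correction over the random
    effects only.
    """
    ll = f_pen
    q = 0
    logdet = 0.0
    if use_y:
        ll -= 0.5 * n_year * np.log(2.0 * np.pi * s2y)
        q += n_year
    if use_p:
        ll -= 0.5 * n_patch * np.log(2.0 * np.pi * s2p)
        q += n_patch
        logdet += float(np.sum(np.log(dp)))
    if use_y:
        # year block of the negative Hessian after eliminating patches
        Syy = S[p:, p:]
        sign, ld = np.linalg.slogdet(Syy)
        if sign <= 0:
            raise FitError("random-effect Hessian not positive definite")
        logdet += ld
    if q:
        ll += 0.5 * q * _LOG2PI - 0.5 * logdet
    return ll


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    patch_codes: np.ndarray,
    year_codes: np.ndarray,
    n_patch: int,
    n_year: int,
    fix_sigma2_patch: float | None = None,
    fix_sigma2_year: float | None = None,
    sigma_start: float = 0.3,
    max_abs_beta: float = 15.0,
    ridge_precision: float = 1e-4,
    patch_levels: np.ndarray | None = None,
    year_levels: np.ndarray | None = None,
) -> GLMMResult:
    """Fit the crossed-random-intercept logistic model by Laplace ML.

    Parameters
    ----------
    y, X
        Binary response and dense fixed-effect design (first column is
        typically the intercept).
    patch_codes, year_codes
        Integer level codes per row.
    fix_sigma2_patch, fix_sigma2_year
        Fix a variance component instead of estimating it; 0 removes the
        factor (the plain logistic limit when both are 0).
    ridge_precision
        Ridge applied to the slopes if quasi-separation drives any |beta|
        beyond ``max_abs_beta``; a :class:`SeparationWarning` is emitted.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    free_p = fix_sigma2_patch is None
    free_y = fix_sigma2_year is None

    state = {"theta": None, "ridge": 0.0}

    def fit_inner(s2p, s2y):
        theta, f, S, dp, C, conv, gnorm, ntop = _inner_mode(
            y, X, patch_codes, year_codes, n_patch, n_year, s2p, s2y,
            state["ridge"], theta0=state["theta"],
        )
        if np.max(np.abs(theta[:p])) > max_abs_beta and state["ridge"] == 0.0:
            warnings.warn(
                "quasi-separation detected (|beta| > %.0f); refitting with a "
                "weak ridge on the slopes" % max_abs_beta,
                SeparationWarning,
            )
            state["ridge"] = ridge_precision
            state["theta"] = None
            theta, f, S, dp, C, conv, gnorm, ntop = _inner_mode(
                y, X, patch_codes, year_codes, n_patch, n_year, s2p, s2y,
                state["ridge"], theta0=None,
            )
        state["theta"] = theta
        return theta, f, S, dp, C, conv, gnorm, ntop

    def marginal(log_s):
        i = 0
        if free_p:
            s2p = float(np.exp(2.0 * np.clip(log_s[i], -10, 4)))
            i += 1
        else:
            s2p = fix_sigma2_patch
        if free_y:
            s2y = float(np.exp(2.0 * np.clip(log_s[i], -10, 4)))
        else:
            s2y = fix_sigma2_year
        theta, f, S, dp, C, conv, gnorm, ntop = fit_inner(s2p, s2y)
        ll = _laplace_loglik(f, S, dp, C, p, s2p, s2y, n_patch, n_year,
                             s2p > 0, s2y > 0)
        return -ll, (s2p, s2y)

    n_free = int(free_p) + int(free_y)
    if n_free:
        x0 = np.full(n_free, np.log(sigma_start))
        res = optimize.minimize(
            lambda v: marginal(v)[0], x0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400},
        )
        neg_ll, (s2p, s2y) = marginal(res.x)
    else:
        neg_ll, (s2p, s2y) = marginal(np.empty(0))

    theta, f, S, dp, C, conv, gnorm, ntop = fit_inner(s2p, s2y)
    ll = _laplace_loglik(f, S, dp, C, p, s2p, s2y, n_patch, n_year,
                         s2p > 0, s2y > 0)
    if not conv and gnorm > 1e-3:
        raise FitError(f"inner Newton failed to converge (grad inf-norm {gnorm:.3g})")

    beta = theta[:p]
    u_year = theta[p:ntop] if s2y > 0 else np.zeros(n_year)
    u_patch = theta[ntop:] if s2p > 0 else np.zeros(n_patch)
    # fixed-effect covariance: beta block of the inverse joint negative Hessian
    try:
        Sinv = linalg.inv(S)
    except linalg.LinAlgError:
        Sinv = np.linalg.pinv(S)
    vcov = Sinv[:p, :p]
    # symmetrise against round-off
    vcov = 0.5 * (vcov + vcov.T)

    n_var = n_free
    return GLMMResult(
        beta=beta,
        vcov=vcov,
        sigma2_patch=float(s2p),
        sigma2_year=float(s2y),
        u_patch=u_patch,
        u_year=u_year,
        loglik=float(ll),
        n=n,
        n_params_fixed=p,
        n_params_var=n_var,
        converged=bool(conv),
        gradient_norm=float(gnorm),
        ridge=state["ridge"],
        patch_levels=patch_levels,
        year_levels=year_levels,
    )


def fit_logistic_newton(y: np.ndarray, X: np.ndarray, tol: float = 1e-10,
                        max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Plain logistic regression by Newton–Raphson; returns (beta, loglik)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None])
        beta = beta + np.linalg.solve(H, g)
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, ll
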