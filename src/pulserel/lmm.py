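"""Random-intercept linear mixed models via profiled REML, with Satterthwaite df.

The models fitted throughout the package are small: y = X b + sum_g Z_g u_g + e
with one or two crossed random-intercept factors, u_g ~ N(0, tau_g I),
e ~ N(0, sigma2 I).  Writing V = sigma2 * W(gamma) with W = I + sum_g gamma_g
Z_g Z_g' and gamma_g = tau_g / sigma2, both the fixed effects and sigma2
profile out of the REML criterion, leaving a G-dimensional optimisation over
log gamma:

    -2 lR(gamma) = log|W| + log|X' W^-1 X| + (n - p) log(r' W^-1 r) + const.

Degrees of freedom for fixed-effect t tests use the Satterthwaite
approximation, df = 2 f^2 / (g' A g), where f = Var(b_j), g its gradient with
respect to theta = (sigma2, tau_1, ...), and A the inverse expected REML
information 0.5 tr(P dV_i P dV_j).  All pieces are closed-form for this
variance structure, so no numerical differentiation is involved.

Fits are cross-checked in the test suite against statsmodels MixedLM and
R's lmerTest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_GAMMA_FLOOR = 1e-10
_PERFECT_FIT_TOL = 1e-12


class DegenerateDesignError(ValueError):
    pass


@dataclass
class LmmFit:
    """Fixed-effect estimates and variance components of a random-intercept LMM."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    df: np.ndarray  # Satterthwaite-approximated, per coefficient
    p_value: np.ndarray
    sigma2: float
    tau: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_obs: int = 0
    method: str = "reml"

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def _design_matrices(groups: dict[str, np.ndarray], n: int) -> dict[str, np.ndarray]:
    out = {}
    for name, labels in groups.items():
        codes, uniques = pd.factorize(np.asarray(labels), sort=True)
        z = np.zeros((n, len(uniques)))
        z[np.arange(n), codes] = 1.0
        out[name] = z
    return out


def fit_lmm(
    y,
    X,
    groups: dict[str, np.ndarray] | None = None,
    names: tuple[str, ...] | None = None,
    compute_df: bool = True,
) -> LmmFit:
    """Fit a linear mixed model with random intercepts for each group factor.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (include the intercept column yourself)
    groups : mapping factor name -> (n,) label array; empty/None gives OLS
    names : fixed-effect names (defaults to x0..x{p-1})
    compute_df : skip the Satterthwaite computation when only the point
        estimate is needed (e.g. inside resampling loops); df is then NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have different lengths")
    if n <= p:
        raise DegenerateDesignError(f"need more observations ({n}) than fixed effects ({p})")
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    groups = groups or {}

    # rank / variance guard on the design
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError("fixed-effect design is rank deficient")

    # OLS; also serves as the degenerate perfect-fit fast path
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    scale = max(sst, float(y @ y), 1.0)
    if sse <= _PERFECT_FIT_TOL * scale or not groups:
        sigma2 = sse / (n - p)
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta_ols / se, np.inf * np.sign(beta_ols))
        df = np.full(p, float(n - p))
        pv = 2 * stats.t.sf(np.abs(t), df)
        return LmmFit(
            names=names,
            beta=beta_ols,
            se=se,
            t_stat=t,
            df=df,
            p_value=pv,
            sigma2=sigma2,
            tau={g: 0.0 for g in groups},
            converged=True,
            n_obs=n,
            method="ols" if not groups else "ols-perfect-fit",
        )

    Z = _design_matrices(groups, n)
    factor_names = list(Z)
    ZZt = {g: Z[g] @ Z[g].T for g in factor_names}
    G = len(factor_names)
    eye = np.eye(n)

    def profiled(log_gamma: np.ndarray):
        gamma = np.exp(np.clip(log_gamma, -30.0, 30.0))
        W = eye.copy()
        for g, lg in zip(factor_names, gamma):
            W += lg * ZZt[g]
        try:
            cf = linalg.cho_factor(W, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_w = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Wi_X = linalg.cho_solve(cf, X, check_finite=False)
        Wi_y = linalg.cho_solve(cf, y, check_finite=False)
        M = X.T @ Wi_X
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        b = np.linalg.solve(M, X.T @ Wi_y)
        r = y - X @ b
        Wi_r = Wi_y - Wi_X @ b
        rwr = float(r @ Wi_r)
        if rwr <= 0:
            rwr = np.finfo(float).tiny
        nll = 0.5 * (logdet_w + logdet_m + (n - p) * np.log(rwr))
        return nll, gamma, cf, M, b, rwr

    def objective(log_gamma: np.ndarray) -> float:
        out = profiled(np.atleast_1d(log_gamma))
        return np.inf if out is None else out[0]

    if G == 1:
        res = optimize.minimize_scalar(
            lambda lg: objective(np.array([lg])), bounds=(-25.0, 25.0), method="bounded",
            options={"xatol": 1e-8},
        )
        best_x, best_fun, converged = np.array([res.x]), res.fun, bool(res.success)
    else:
        starts = [np.zeros(G), np.full(G, np.log(0.1)), np.full(G, np.log(10.0))]
        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400 * G},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success) or converged
        best_x, best_fun = best.x, best.fun
    out = profiled(np.atleast_1d(best_x))
    if out is None or not np.isfinite(best_fun):
        raise DegenerateDesignError("REML criterion is not finite at the optimum")
    _, gamma, cf, M, beta, rwr = out
    gamma = np.maximum(gamma, _GAMMA_FLOOR)
    sigma2 = rwr / (n - p)
    tau = {g: float(sigma2 * lg) for g, lg in zip(factor_names, gamma)}

    C = sigma2 * np.linalg.inv(M)  # Var(beta_hat) = (X' V^-1 X)^-1
    se = np.sqrt(np.maximum(np.diag(C), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))

    if compute_df:
        df = _satterthwaite_df(X, C, cf, sigma2, [ZZt[g] for g in factor_names], eye)
    else:
        df = np.full(p, np.nan)
    with np.errstate(invalid="ignore"):
        pv = 2 * stats.t.sf(np.abs(t), df)
    return LmmFit(
        names=names,
        beta=beta,
        se=se,
        t_stat=t,
        df=df,
        p_value=pv,
        sigma2=float(sigma2),
        tau=tau,
        converged=converged,
        n_obs=n,
        method="reml",
    )


def _satterthwaite_df(X, C, cf, sigma2, zzt_list, eye) -> np.ndarray:
    """Satterthwaite df per fixed effect from the expected REML information.

    theta = (sigma2, tau_1, ..., tau_G); dV/dsigma2 = I, dV/dtau_g = Z_g Z_g'.
    """
    n, p = X.shape
    derivs = [eye] + zzt_list
    q = len(derivs)
    # V^-1 = W^-1 / sigma2; reuse the Cholesky factor of W
    Vi = linalg.cho_solve(cf, eye, check_finite=False) / sigma2
    Vi_X = Vi @ X
    # P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 ; note C = (X'V^-1X)^-1
    P = Vi - Vi_X @ C @ Vi_X.T
    PV = [P @ D for D in derivs]
    info = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            info[i, j] = info[j, i] = 0.5 * float(np.einsum("ij,ji->", PV[i], PV[j]))
    A = np.linalg.pinv(info)

    # grad of f_j = Var(b_j) wrt theta_i: [C X'V^-1 dV_i V^-1 X C]_jj
    dfs = np.empty(p)
    K = C @ Vi_X.T  # p x n
    for j in range(p):
        f = C[j, j]
        kj = K[j]  # (n,)
        grad = np.array([float(kj @ D @ kj) for D in derivs])
        denom = float(grad @ A @ grad)
        if denom <= 0 or not np.isfinite(denom) or f <= 0:
            dfs[j] = float(n - p)
        else:
            dfs[j] = max(2.0 * f * f / denom, 1.0)
    return dfs
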