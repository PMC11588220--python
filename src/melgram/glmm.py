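"""Maximum-likelihood binomial GLMM with a single random intercept.

The model is a logistic regression whose linear predictor carries one
scalar random intercept per grouping unit (here: participant),

    logit P(y_ij = 1) = x_ij' beta + u_i,    u_i ~ N(0, sigma_u^2).

The marginal likelihood integrates each group's Bernoulli product over
``u_i`` with Gauss-Hermite quadrature, which is accurate for a scalar
random effect, and is maximised with L-BFGS-B over ``(beta, sigma_u)``
with ``sigma_u >= 0`` (the boundary is a legitimate optimum when groups
are homogeneous).  Standard errors come from the inverse of a central-
difference Hessian of the negative log-likelihood at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["GlmmFit", "fit_binomial_glmm"]


@dataclass(frozen=True)
class GlmmFit:
    """A fitted random-intercept binomial GLMM."""

    formula: str
    params: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, z, p
    sigma_u: float
    loglik: float
    nobs: int
    n_groups: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        """Number of estimated parameters: fixed effects + the RE variance."""
        return len(self.params) + 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * np.log(self.nobs)

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return tuple(self.params.index)

    def summary(self) -> str:
        lines = [f"binomial GLMM: {self.formula}",
                 f"groups={self.n_groups}  obs={self.nobs}  "
                 f"loglik={self.loglik:.3f}  BIC={self.bic:.3f}  "
                 f"sigma_u={self.sigma_u:.3f}  converged={self.converged}"]
        lines.append(self.params.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def _group_loglik(eta_base: np.ndarray, y: np.ndarray, starts: np.ndarray,
                  sigma: float, nodes: np.ndarray, weights: np.ndarray) -> float:
    """Sum over groups of log integral of the Bernoulli product over u."""
    # log p(y | u) per observation per node
    u = sigma * nodes  # (Q,)
    eta = eta_base[:, None] + u[None, :]  # (N, Q)
    # log Bernoulli: y*eta - log(1+exp(eta))
    ll_obs = np.where(y[:, None] == 1, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta))
    block = np.add.reduceat(ll_obs, starts[:-1], axis=0)  # (G, Q)
    return float(special.logsumexp(block, axis=1, b=weights).sum())


def fit_binomial_glmm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    *,
    formula: str = "",
    n_quad: int = 25,
    maxiter: int = 500,
) -> GlmmFit:
    """Fit the random-intercept logistic model by marginal ML.

    Parameters
    ----------
    y : 0/1 responses.
    X : design matrix with named columns (include an intercept explicitly).
    groups : grouping labels, one per row.
    n_quad : number of Gauss-Hermite nodes for the scalar integral.
    """
    y = np.asarray(y, dtype=int)
    Xv = X.to_numpy(dtype=float)
    if y.shape[0] != Xv.shape[0] or y.shape[0] != len(groups):
        raise ValueError("y, X and groups must have matching lengths")
    if Xv.shape[0] == 0:
        raise ValueError("empty data")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")

    # sort rows by group so each group is one contiguous block
    order = np.argsort(np.asarray(groups), kind="stable")
    y = y[order]
    Xv = Xv[order]
    g_sorted = np.asarray(groups)[order]
    _, first = np.unique(g_sorted, return_index=True)
    starts = np.append(np.sort(first), len(y))
    n_groups = len(starts) - 1

    # physicists' Hermite nodes -> standard normal via x = sqrt(2) t
    t, w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = np.sqrt(2.0) * t
    weights = w / np.sqrt(np.pi)

    p = Xv.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta, sigma = theta[:p], abs(theta[p])
        return -_group_loglik(Xv @ beta, y, starts, sigma, nodes, weights)

    # warm start at the pooled logistic solution
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.GLM(y, Xv, family=sm.families.Binomial()).fit().params
    x0 = np.append(start_beta, 0.3)
    bounds = [(None, None)] * p + [(0.0, None)]
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    beta_hat, sigma_hat = res.x[:p], float(res.x[p])
    loglik = -float(res.fun)

    cov, hess_ok = _hessian_cov(nll, res.x, boundary=sigma_hat < 1e-6)
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_hat / se, np.nan)
    params = pd.DataFrame({
        "estimate": beta_hat,
        "se": se,
        "ci_low": beta_hat - zcrit * se,
        "ci_high": beta_hat + zcrit * se,
        "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
    }, index=list(X.columns))

    converged = bool(res.success) and hess_ok
    fit = GlmmFit(
        formula=formula or ("choice ~ " + " + ".join(X.columns) + " + (1 | participant)"),
        params=params,
        sigma_u=sigma_hat,
        loglik=loglik,
        nobs=len(y),
        n_groups=n_groups,
        converged=converged,
        diagnostics={"optimizer_message": str(res.message), "n_quad": n_quad,
                     "grad_norm": float(np.linalg.norm(res.jac)), "hessian_pd": hess_ok},
    )
    if not converged:
        warnings.warn(f"GLMM fit flagged as non-converged: {fit.diagnostics}", stacklevel=2)
    return fit


def _hessian_cov(f, x, *, boundary: bool, h: float = 1e-4) -> tuple[np.ndarray, bool]:
    """Covariance of the fixed effects via a central-difference Hessian.

    When sigma_u sits on the zero boundary its row/column is dropped before
    inversion (the Wald approximation is invalid there anyway).
    """
    n = len(x)
    idx = list(range(n - 1)) if boundary else list(range(n))
    m = len(idx)
    H = np.zeros((m, m))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for a in range(m):
        for b in range(a, m):
            ia, ib = idx[a], idx[b]
            ea = np.zeros(n); ea[ia] = steps[ia]
            eb = np.zeros(n); eb[ib] = steps[ib]
            if a == b:
                val = (f(x + ea) - 2 * f0 + f(x - ea)) / steps[ia] ** 2
            else:
                val = (f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)) \
                    / (4 * steps[ia] * steps[ib])
            H[a, b] = H[b, a] = val
    try:
        cov_small = np.linalg.inv(H)
        ok = bool(np.all(np.diag(cov_small)[: len(idx)] > 0))
    except np.linalg.LinAlgError:
        cov_small = np.full((m, m), np.nan)
        ok = False
    cov = np.full((n, n), np.nan)
    for a in range(m):
        for b in range(m):
            cov[idx[a], idx[b]] = cov_small[a, b]
    return cov, ok
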