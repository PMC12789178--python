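"""Gaussian linear mixed models with crossed random intercepts.

The repeatability analysis needs variance components for several
*crossed* grouping factors (female, female-year, nest-box) in one
model.  This module fits

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2 I)

by (RE)ML, profiling out ``beta`` and the residual variance and
optimising the variance ratios ``theta_k = s2_k / s2 >= 0``.

The profiled criterion follows the standard sparse-Cholesky approach:
with ``Lambda = diag(sqrt(theta))`` block-wise and the penalised least
squares residual r2(theta) = min ||y - X beta - Z Lambda u||^2 + ||u||^2,

    REML deviance = log|L_Z|^2 + log|L_X|^2 + (n-p)(1 + log(2 pi r2/(n-p)))
    ML   deviance = log|L_Z|^2 +              n(1 + log(2 pi r2/n))

where ``L_Z`` is the Cholesky factor of ``Lambda' Z'Z Lambda + I`` and
``L_X`` that of the profiled fixed-effect cross-product.  Components on
the boundary (theta = 0) are handled exactly.  All cross-products are
formed once; each objective evaluation costs one dense Cholesky of the
(number of random levels)^2 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

__all__ = ["CrossedLMMFit", "fit_crossed_lmm", "lrt"]


class LMMError(RuntimeError):
    pass


@dataclass
class CrossedLMMFit:
    """Result of a crossed random-intercept (RE)ML fit."""

    varcomps: dict[str, float]  # per-factor variance (response units^2)
    sigma2: float  # residual variance
    loglik: float  # maximised (restricted) log-likelihood
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    fixed_names: list[str]
    reml: bool
    n_obs: int
    n_levels: dict[str, int]
    theta: np.ndarray
    converged: bool
    optimizer_message: str = ""

    @property
    def total_variance(self) -> float:
        return float(sum(self.varcomps.values()) + self.sigma2)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"component": k, "variance": v, "n_levels": self.n_levels[k]}
            for k, v in self.varcomps.items()
        ]
        rows.append({"component": "residual", "variance": self.sigma2, "n_levels": self.n_obs})
        return pd.DataFrame(rows)


def _encode(levels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(levels))
    if (codes < 0).any():
        raise LMMError("missing values in a grouping factor")
    return codes, len(uniques)


def fit_crossed_lmm(
    y,
    X,
    groups: "dict[str, np.ndarray]",
    reml: bool = True,
    fixed_names: "list[str] | None" = None,
    start: "np.ndarray | None" = None,
) -> CrossedLMMFit:
    """Fit a Gaussian LMM with crossed random intercepts.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (must include the intercept column)
    groups : mapping factor name -> length-n label array
    reml : restricted (True) or full maximum likelihood
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise LMMError("y and X have incompatible shapes")
    if n <= p:
        raise LMMError("more fixed-effect columns than observations")
    if np.linalg.matrix_rank(X) < p:
        raise LMMError("fixed-effect design is rank deficient")

    names = list(groups)
    codes, sizes = [], []
    for name in names:
        c, m = _encode(groups[name])
        codes.append(c)
        sizes.append(m)
    q = int(np.sum(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    cols = np.concatenate([c + o for c, o in zip(codes, offsets[:-1])])
    rows = np.tile(np.arange(n), len(names))
    Z = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, q)
    )

    # cross-products, formed once
    A = np.asarray((Z.T @ Z).todense())
    ZtX = np.asarray(Z.T @ X)
    Zty = np.asarray(Z.T @ y).ravel()
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    block = np.concatenate(
        [np.full(m, i) for i, m in enumerate(sizes)]
    )  # factor index per random column

    def profile(theta: np.ndarray):
        s = np.sqrt(theta)[block]
        M = (s[:, None] * A) * s[None, :]
        M[np.diag_indices_from(M)] += 1.0
        L, low = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet_LZ2 = 2.0 * float(np.sum(np.log(np.diag(L))))
        RZX = linalg.solve_triangular(
            L, s[:, None] * ZtX, lower=True, check_finite=False
        )
        cu = linalg.solve_triangular(L, s * Zty, lower=True, check_finite=False)
        RXtRX = XtX - RZX.T @ RZX
        LX = linalg.cholesky(RXtRX, lower=True)
        logdet_LX2 = 2.0 * float(np.sum(np.log(np.diag(LX))))
        rhs = Xty - RZX.T @ cu
        beta = linalg.cho_solve((LX, True), rhs)
        pwrss = max(yty - float(cu @ cu) - float(rhs @ beta), 1e-300)
        return logdet_LZ2, logdet_LX2, beta, pwrss, LX

    def deviance(theta: np.ndarray) -> float:
        try:
            logdet_LZ2, logdet_LX2, _, pwrss, _ = profile(theta)
        except np.linalg.LinAlgError:
            return np.inf
        if reml:
            dof = n - p
            return logdet_LZ2 + logdet_LX2 + dof * (1.0 + np.log(2 * np.pi * pwrss / dof))
        return logdet_LZ2 + n * (1.0 + np.log(2 * np.pi * pwrss / n))

    k = len(names)
    if start is None:
        start = np.full(k, 0.5)
    best = None
    for x0 in (start, np.full(k, 0.05)):
        res = optimize.minimize(
            deviance,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1e6)] * k,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not np.isfinite(best.fun):
        raise LMMError(f"LMM optimisation failed: {best.message}")
    theta = np.maximum(best.x, 0.0)
    # snap tiny ratios to the boundary (singular fit, e.g. a null component)
    theta[theta < 1e-8] = 0.0

    logdet_LZ2, logdet_LX2, beta, pwrss, LX = profile(theta)
    dof = n - p if reml else n
    sigma2 = pwrss / dof
    dev = deviance(theta)
    varcomps = {name: float(theta[i] * sigma2) for i, name in enumerate(names)}
    cov = linalg.cho_solve((LX, True), np.eye(p)) * sigma2
    cov = (cov + cov.T) / 2.0
    se = np.sqrt(np.diag(cov))
    if fixed_names is None:
        fixed_names = [f"x{i}" for i in range(p)]
    return CrossedLMMFit(
        varcomps=varcomps,
        sigma2=float(sigma2),
        loglik=float(-dev / 2.0),
        beta=np.asarray(beta),
        se=se,
        cov_beta=cov,
        fixed_names=list(fixed_names),
        reml=reml,
        n_obs=n,
        n_levels=dict(zip(names, sizes)),
        theta=theta,
        converged=bool(best.success),
        optimizer_message=str(best.message),
    )


def lrt(full_loglik: float, reduced_loglik: float, df: int = 1) -> tuple[float, int, float]:
    """Likelihood-ratio test statistic, df and chi-square p-value.

    The statistic is clipped at zero (numerical optimisers can leave
    the full model's likelihood a hair below the reduced one when the
    extra parameter is on the boundary).
    """
    stat = max(2.0 * (full_loglik - reduced_loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p
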