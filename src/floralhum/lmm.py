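"""Maximum-likelihood linear mixed model with one random intercept.

The humidity-structure models all share one covariance structure: a
Gaussian random intercept per flower plus iid residuals,

    y = X beta + Z u + e,   u ~ N(0, s2_g I),   e ~ N(0, s2 I),

with Z the flower indicator matrix. Writing the variance ratio
lam = s2_g / s2, the marginal covariance is s2 * (I + lam Z Z'), whose
blocks invert in closed form (Sherman-Morrison per group). Both beta
and s2 profile out analytically, leaving a smooth one-dimensional
profile log-likelihood in lam that is maximized by a log-grid sweep
plus bounded refinement. ML (not REML) is used throughout so that AIC
is comparable across models with different fixed effects.

The boundary lam = 0 (no between-flower variance) is a legal optimum
and is reported, not treated as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


class LMMError(ValueError):
    pass


@dataclass
class LMMFit:
    """ML estimates for the random-intercept model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2: float  # residual variance
    sigma2_group: float  # random-intercept variance
    log_likelihood: float
    n_obs: int
    n_groups: int
    n_fixed: int
    boundary: bool  # random-intercept variance fit at 0
    single_group: bool = False  # fixed-effects fallback (one flower)
    column_names: list[str] = field(default_factory=list)

    @property
    def k_parameters(self) -> int:
        """Free parameters counted for AIC: fixed effects + 2 variances."""
        return self.n_fixed + 2

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k_parameters

    def random_intercepts(self, X, y, groups) -> np.ndarray:
        """BLUPs of the per-group intercepts at the ML estimates."""
        resid = y - X @ self.beta
        out = np.zeros(self.n_groups)
        lam = self.sigma2_group / self.sigma2 if self.sigma2 > 0 else 0.0
        for j in range(self.n_groups):
            m = groups == j
            nj = int(m.sum())
            out[j] = lam / (1.0 + lam * nj) * resid[m].sum()
        return out


def _group_weights(group_sizes, lam):
    """Per-group Sherman-Morrison weight lam / (1 + lam * n_j)."""
    return lam / (1.0 + lam * group_sizes)


def _vinv_apply(a, codes, weights):
    """Apply V^-1 = I - diag(w) 11' blockwise to a vector or matrix."""
    if a.ndim == 1:
        sums = np.bincount(codes, weights=a)
        return a - weights[codes] * sums[codes]
    out = np.empty_like(a)
    for j in range(a.shape[1]):
        sums = np.bincount(codes, weights=a[:, j])
        out[:, j] = a[:, j] - weights[codes] * sums[codes]
    return out


def _profile_loglik(X, y, codes, group_sizes, lam):
    n = len(y)
    w = _group_weights(group_sizes, lam)
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    Vx = _vinv_apply(X, codes, w)
    Vy = _vinv_apply(y, codes, w)
    xtvx = X.T @ Vx
    xtvy = X.T @ Vy
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - X @ beta
    Vr = _vinv_apply(resid, codes, w)
    rss = float(resid @ Vr)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2, xtvx


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    column_names: list[str] | None = None,
) -> LMMFit:
    """Fit the random-intercept model by profile ML.

    ``groups`` is any array of hashable labels; a single group triggers
    a fixed-effects (OLS) fallback with the group variance pinned to 0
    and ``single_group`` flagged.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim != 2 or len(y) != len(X):
        raise LMMError("X must be 2-D and aligned with y")
    n, p = X.shape
    if n <= p:
        raise LMMError(f"{n} observations cannot identify {p} fixed effects")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _aliased_columns(X, column_names)
        raise LMMError(f"singular fixed-effects design; aliased columns: {bad}")
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    g = int(codes.max()) + 1
    sizes = np.bincount(codes)

    if g == 1:
        ll, beta, sigma2, xtvx = _profile_loglik(X, y, codes, sizes, 0.0)
        return LMMFit(
            beta=beta, beta_cov=sigma2 * np.linalg.inv(xtvx), sigma2=sigma2,
            sigma2_group=0.0, log_likelihood=ll, n_obs=n, n_groups=1,
            n_fixed=p, boundary=True, single_group=True,
            column_names=list(column_names or []),
        )

    def neg_ll_log(t):
        return -_profile_loglik(X, y, codes, sizes, np.exp(t))[0]

    # coarse sweep in log(lam), then bounded refinement around the best
    grid = np.linspace(np.log(1e-8), np.log(1e6), 57)
    vals = np.array([neg_ll_log(t) for t in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_ll_log, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll, beta, sigma2, xtvx = _profile_loglik(X, y, codes, sizes, lam)
    ll0, beta0, sigma20, xtvx0 = _profile_loglik(X, y, codes, sizes, 0.0)
    boundary = ll0 >= ll
    if boundary:
        lam, ll, beta, sigma2, xtvx = 0.0, ll0, beta0, sigma20, xtvx0
    return LMMFit(
        beta=beta,
        beta_cov=sigma2 * np.linalg.inv(xtvx),
        sigma2=sigma2,
        sigma2_group=lam * sigma2,
        log_likelihood=ll,
        n_obs=n,
        n_groups=g,
        n_fixed=p,
        boundary=boundary,
        column_names=list(column_names or []),
    )


def _aliased_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    """Identify columns not adding rank, for error messages."""
    keep: list[int] = []
    bad: list[int] = []
    for j in range(X.shape[1]):
        cols = keep + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            keep.append(j)
        else:
            bad.append(j)
    if names:
        return [names[j] for j in bad]
    return [str(j) for j in bad]


def marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
    sigma2_group: float,
) -> float:
    """Marginal Gaussian log-likelihood at given parameters (blockwise).

    Used for likelihood-ratio reporting; tests compare it against a
    dense multivariate-normal evaluation.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    _, codes = np.unique(np.asarray(groups), return_inverse=True)
    resid = y - X @ np.asarray(beta, float)
    n = len(y)
    ll = -0.5 * n * np.log(2 * np.pi)
    for j in range(codes.max() + 1):
        r = resid[codes == j]
        nj = len(r)
        # V_j = sigma2 I + sigma2_group 11'
        denom = sigma2 + sigma2_group * nj
        logdet = (nj - 1) * np.log(sigma2) + np.log(denom)
        quad = (r @ r) / sigma2 - (sigma2_group / (sigma2 * denom)) * r.sum() ** 2
        ll -= 0.5 * (logdet + quad)
    return float(ll)
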