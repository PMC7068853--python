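"""Phylogenetically controlled regression of peak floral humidity.

Species are related, so their peak humidity values are not independent
observations. Generalized least squares with a phylogenetic residual
correlation accounts for this. Two correlation structures are offered,
both on the height-normalized tree (total tree height scaled to 1):

* **Brownian motion (BM):** corr(i, j) = shared root-to-MRCA path
  length divided by tree height.
* **Ornstein-Uhlenbeck (OU):** the root-anchored OU process with rate
  alpha gives tip covariance proportional to
  exp(-alpha d_ij) (1 - exp(-2 alpha t_ij)), where d_ij is the
  patristic distance and t_ij the root-to-MRCA depth, both on the
  height-normalized tree; the correlation scales this by the tip
  variances. As alpha -> 0 this converges entrywise to the BM matrix;
  for large alpha it decays as exp(-alpha d_ij) (the Martins-Hansen
  structure). Because alpha is tied to the height normalization, its
  numeric value is comparable only across fits using this convention.

The response is log peak humidity (natural log, so peaks must be
positive); predictors are flower span (mm) and binary dummies for
floral type (flower = 0, inflorescence = 1) and outdoor growth. When
requested, alpha is estimated by profile maximum likelihood over a
log-spaced grid with golden-section refinement. Full models are
compared against the grand-mean null, and OU against BM, by AIC and
likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


class PhyloError(ValueError):
    pass


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(source), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise PhyloError(f"negative branch length {edge.length}")
    return tree


def _tip_depths_and_distances(tree: dendropy.Tree):
    """Taxon labels, root-to-tip depths, and the patristic matrix."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise PhyloError("duplicate tip labels in tree")
    depths = np.array([lf.root_distance for lf in leaves], float)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            dist[i, j] = dist[j, i] = d
    return labels, depths, dist


def build_correlation(
    tree: dendropy.Tree,
    model: str = "BM",
    alpha: float | None = None,
    taxa: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic tip correlation matrix under BM or OU.

    Returns (matrix, tip labels in matrix order), restricted and
    reordered to ``taxa`` when given. Raises if the result is not
    numerically positive definite.
    """
    labels, depths, dist = _tip_depths_and_distances(tree)
    height = float(depths.max())
    if height <= 0:
        raise PhyloError("tree has zero height")
    # shared path from root to MRCA = (depth_i + depth_j - d_ij) / 2
    shared = (depths[:, None] + depths[None, :] - dist) / 2.0
    if model.upper() == "BM":
        corr = shared / height
        np.fill_diagonal(corr, depths / height)
    elif model.upper() == "OU":
        if alpha is None or alpha <= 0:
            raise PhyloError("OU correlation requires alpha > 0")
        d = dist / height
        t = shared / height
        np.fill_diagonal(t, depths / height)
        cov = np.exp(-alpha * d) * -np.expm1(-2.0 * alpha * t)
        v = np.sqrt(np.diag(cov))
        corr = cov / np.outer(v, v)
    else:
        raise PhyloError(f"unknown correlation model {model!r}")
    if taxa is not None:
        missing = [t for t in taxa if t not in labels]
        if missing:
            raise PhyloError(f"taxa absent from tree: {missing}")
        idx = [labels.index(t) for t in taxa]
        corr = corr[np.ix_(idx, idx)]
        labels = list(taxa)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    # zero-length terminal branches give numerically singular matrices;
    # only genuinely negative spectra are rejected
    if eigmin < -1e-8:
        raise PhyloError(
            f"correlation matrix not positive definite (min eigenvalue {eigmin:.3e})"
        )
    return corr, labels


@dataclass
class ComparativeFit:
    """GLS fit of (log) peak humidity under a phylogenetic correlation."""

    correlation_model: str  # "BM" | "OU"
    alpha: float | None
    coef_names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    sigma2: float
    log_likelihood: float
    aic: float
    n: int
    species: list[str]

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        lo = self.coefficients - q * self.se
        hi = self.coefficients + q * self.se
        return np.column_stack([lo, hi])

    def effect_table(self) -> pd.DataFrame:
        """Raw and back-transformed (exponentiated) effect sizes."""
        ci = self.conf_int()
        return pd.DataFrame({
            "parameter": self.coef_names,
            "estimate": self.coefficients,
            "se": self.se,
            "back_transformed": np.exp(self.coefficients),
            "bt_ci_low": np.exp(ci[:, 0]),
            "bt_ci_high": np.exp(ci[:, 1]),
            "t": self.tvalues,
            "df": self.df_resid,
            "p": self.pvalues,
        })


def _gls_ml(y, X, corr):
    """Profile-ML GLS under a fixed correlation matrix."""
    n = len(y)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # semi-definite edge case (e.g. effectively identical tips)
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    wy = np.linalg.solve(L, y)
    wX = np.linalg.solve(L, X)
    beta, _, rank, _ = np.linalg.lstsq(wX, wy, rcond=None)
    if rank < X.shape[1]:
        raise PhyloError("collinear predictors in GLS design")
    resid = wy - wX @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    cov = sigma2 * n / (n - X.shape[1]) * np.linalg.inv(wX.T @ wX)
    return beta, cov, sigma2, ll


def prepare_traits(
    table: pd.DataFrame,
    response: str = "delta_rh_max",
    log_response: bool = True,
) -> pd.DataFrame:
    """Validate and transform the comparative trait table.

    Expects columns ``species``, the response, ``span``, ``floral_type``
    (0/1 or flower/inflorescence) and ``grown_outside`` (0/1 or bool).
    Rows with missing values are dropped (complete cases).
    """
    df = table.copy()
    required = ["species", response, "span", "floral_type", "grown_outside"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PhyloError(f"trait table missing columns {missing}")
    df = df.dropna(subset=required)
    if df["floral_type"].dtype == object:
        df["floral_type"] = (df["floral_type"] == "inflorescence").astype(int)
    df["grown_outside"] = df["grown_outside"].astype(int)
    if log_response:
        if (df[response] <= 0).any():
            bad = df.loc[df[response] <= 0, "species"].tolist()
            raise PhyloError(f"non-positive response, cannot log-transform: {bad}")
        df["response"] = np.log(df[response])
    else:
        df["response"] = df[response].astype(float)
    return df


ALPHA_GRID = np.geomspace(1e-4, 1e3, 61)


def pgls_fit(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    correlation_model: str = "BM",
    alpha: float | None = None,
    estimate_alpha: bool = False,
    predictors: tuple[str, ...] = ("span", "floral_type", "grown_outside"),
) -> ComparativeFit:
    """Phylogenetic GLS of the prepared trait table.

    ``traits`` must come from :func:`prepare_traits` (it carries the
    ``response`` column). ``predictors=()`` fits the grand-mean null
    model. With ``estimate_alpha`` the OU rate is chosen by profile ML
    over a log-spaced grid with golden-section refinement.
    """
    species = traits["species"].tolist()
    if len(species) != len(set(species)):
        raise PhyloError("duplicate species in trait table")
    y = traits["response"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(y))] + [traits[p].to_numpy(float) for p in predictors]
    )
    names = ["intercept", *predictors]
    p = X.shape[1]
    if len(y) < p + 2:
        raise PhyloError("need at least 2 more species than coefficients")

    model = correlation_model.upper()
    if model == "BM":
        corr, _ = build_correlation(tree, "BM", taxa=species)
        alpha_hat = None
        k_alpha = 0
        beta, cov, sigma2, ll = _gls_ml(y, X, corr)
    elif model == "OU":
        if estimate_alpha:
            def nll(log_a):
                c, _ = build_correlation(tree, "OU", float(np.exp(log_a)), species)
                return -_gls_ml(y, X, c)[3]

            grid = np.log(ALPHA_GRID)
            vals = np.array([nll(t) for t in grid])
            i = int(np.argmin(vals))
            lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
            res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-8})
            alpha_hat = float(np.exp(res.x))
            k_alpha = 1
        else:
            if alpha is None or alpha <= 0:
                raise PhyloError("fixed-alpha OU fit requires alpha > 0")
            alpha_hat = float(alpha)
            k_alpha = 0
        corr, _ = build_correlation(tree, "OU", alpha_hat, species)
        beta, cov, sigma2, ll = _gls_ml(y, X, corr)
    else:
        raise PhyloError(f"unknown correlation model {correlation_model!r}")

    se = np.sqrt(np.diag(cov))
    df_resid = len(y) - p
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    k = p + 1 + k_alpha  # coefficients + residual variance (+ alpha)
    return ComparativeFit(
        correlation_model=model,
        alpha=alpha_hat,
        coef_names=names,
        coefficients=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        df_resid=df_resid,
        sigma2=sigma2,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * k,
        n=len(y),
        species=species,
    )


@dataclass(frozen=True)
class ModelComparison:
    delta_aic: float
    lr_statistic: float
    df: int | None
    p_value: float | None


def compare_models(
    fit_a: ComparativeFit, fit_b: ComparativeFit, nested: bool = False
) -> ModelComparison:
    """Compare two comparative fits sharing response and species.

    ``fit_a`` is the richer model. Reports AIC difference (b - a) and
    the likelihood-ratio statistic 2(ll_a - ll_b); when ``nested``, a
    chi-square reference with df equal to the parameter-count gap gives
    the p value.
    """
    if fit_a.species != fit_b.species:
        raise PhyloError("fits cover different species sets")
    lr = 2.0 * (fit_a.log_likelihood - fit_b.log_likelihood)
    delta_aic = fit_b.aic - fit_a.aic
    if nested:
        ka = len(fit_a.coef_names) + 1 + (1 if fit_a.alpha is not None else 0)
        kb = len(fit_b.coef_names) + 1 + (1 if fit_b.alpha is not None else 0)
        df = max(ka - kb, 1)
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        return ModelComparison(delta_aic, lr, df, p)
    return ModelComparison(delta_aic, lr, None, None)
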