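"""GO-aggregated differential expression with empirical dispersion.

Expression tables carry per-gene FPKM for two conditions (WT and knockout)
and the fold change log2(WT/KO). Because the variance of RNA-seq fold
changes depends strongly on expression level, genes are binned by log2
geometric-mean expression, per-bin mean and variance of the fold change are
fitted with quadratics, and each gene is standardized to a Z-score against
those fits. Annotation terms aggregate member fold changes; a one-sample
two-sided t-test on member Z-scores gives a per-term p-value, corrected
across terms with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("gene", "fpkm_wt", "fpkm_ko", "log2fc", "length")


def filter_genes(expr: pd.DataFrame, min_fpkm: float = 1.0) -> pd.DataFrame:
    """Keep genes whose geometric-mean FPKM exceeds ``min_fpkm`` (strict)."""
    if expr.empty:
        raise ValueError("empty expression table")
    gm = np.sqrt(expr["fpkm_wt"].to_numpy() * expr["fpkm_ko"].to_numpy())
    return expr[gm > min_fpkm].reset_index(drop=True)


@dataclass
class DispersionFit:
    """Quadratic fits of fold-change mean and variance vs expression."""

    bin_edges: np.ndarray  # in log2 geometric-mean FPKM
    bin_centers: np.ndarray
    bin_mean: np.ndarray
    bin_var: np.ndarray
    mean_coef: np.ndarray  # numpy polynomial coefficients, highest first
    var_coef: np.ndarray
    x_range: tuple[float, float]

    def mu(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, *self.x_range)
        return np.polyval(self.mean_coef, x)

    def sigma2(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, *self.x_range)
        return np.polyval(self.var_coef, x)


def _log2_gm(expr: pd.DataFrame) -> np.ndarray:
    return 0.5 * (
        np.log2(expr["fpkm_wt"].to_numpy()) + np.log2(expr["fpkm_ko"].to_numpy())
    )


def fit_dispersion(expr: pd.DataFrame, n_bins: int = 20) -> DispersionFit:
    """Equal-count expression bins; quadratic fits of per-bin mean/variance.

    Ties in expression are broken by gene id so the binning is
    deterministic.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if len(expr) < 200:
        raise ValueError(f"need >= 200 filtered genes, have {len(expr)}")
    x = _log2_gm(expr)
    lfc = expr["log2fc"].to_numpy()
    order = np.lexsort((expr["gene"].to_numpy(), x))
    xs, ls = x[order], lfc[order]
    groups = np.array_split(np.arange(len(xs)), n_bins)
    centers = np.array([xs[g].mean() for g in groups])
    means = np.array([ls[g].mean() for g in groups])
    variances = np.array([ls[g].var(ddof=1) for g in groups])
    edges = np.concatenate([[xs[0]], [xs[g[-1]] for g in groups]])
    mean_coef = np.polyfit(centers, means, 2)
    var_coef = np.polyfit(centers, variances, 2)
    return DispersionFit(
        edges, centers, means, variances, mean_coef, var_coef,
        (float(centers[0]), float(centers[-1])),
    )


def gene_zscores(expr: pd.DataFrame, fit: DispersionFit) -> pd.Series:
    """Standardized fold change Z = (log2fc - mu(e)) / sigma(e) per gene."""
    x = _log2_gm(expr)
    s2 = fit.sigma2(x)
    if np.any(s2 <= 1e-10):  # zero up to polynomial-fit float noise
        bad = expr["gene"].to_numpy()[s2 <= 1e-10][0]
        raise ValueError(
            f"non-positive fitted variance (first at gene {bad!r}); "
            "dispersion fit degenerate on this range"
        )
    z = (expr["log2fc"].to_numpy() - fit.mu(x)) / np.sqrt(s2)
    return pd.Series(z, index=expr["gene"].to_numpy(), name="z")


def aggregate_go(
    z: pd.Series,
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Aggregate fold changes per annotation term and test member Z-scores.

    ``annotation`` maps gene -> term (two columns). Terms with at least
    ``min_genes`` genes present in ``expr`` are scored: aggregated fold
    change = mean member log2fc; one-sample two-sided t-test of member
    Z-scores against zero; BH correction across tested terms. Returned
    sorted by aggregated fold change (most downregulated first).
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    lfc = pd.Series(expr["log2fc"].to_numpy(), index=expr["gene"].to_numpy())
    ann = annotation[annotation["gene"].isin(lfc.index)]
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        genes = sub["gene"].unique()
        if len(genes) < min_genes:
            continue
        zs = z.loc[genes].to_numpy()
        agg = float(lfc.loc[genes].mean())
        if np.std(zs, ddof=1) == 0:
            t_stat, p, degenerate = np.nan, 1.0, True
        else:
            res = stats.ttest_1samp(zs, 0.0)
            t_stat, p, degenerate = float(res.statistic), float(res.pvalue), False
        rows.append((term, len(genes), agg, t_stat, p, degenerate))
    if not rows:
        raise ValueError(f"no terms with >= {min_genes} qualifying genes")
    out = pd.DataFrame(
        rows, columns=["term", "n_genes", "agg_log2fc", "t", "p", "degenerate"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("agg_log2fc").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def rank_conditional_slope_test(
    response: np.ndarray,
    covariate_a: np.ndarray,
    covariate_b: np.ndarray,
    n_quantiles: int = 5,
) -> dict:
    """Does the response depend on covariate b once a is accounted for?

    All three variables are rank-transformed; the response ranks are
    regressed on both covariate ranks and the two-sided t-test p-value of
    the coefficient on b is returned, together with a quantile-by-quantile
    table of mean response over the (a, b) plane.
    """
    response = np.asarray(response, dtype=float)
    a = np.asarray(covariate_a, dtype=float)
    b = np.asarray(covariate_b, dtype=float)
    n = len(response)
    if n < 30 or len(a) != n or len(b) != n:
        raise ValueError("need >= 30 complete observations")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rr = stats.rankdata(response)
    for name, r in (("a", ra), ("b", rb), ("response", rr)):
        if len(np.unique(r)) < 3:
            raise ValueError(f"ties collapse {name} to < 3 distinct ranks")
    if abs(np.corrcoef(ra, rb)[0, 1]) >= 1.0 - 1e-12:
        raise ValueError("covariates have collinear ranks")
    X = np.column_stack([np.ones(n), ra, rb])
    beta, _, _, _ = np.linalg.lstsq(X, rr, rcond=None)
    resid = rr - X @ beta
    dof = n - 3
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    t_b = beta[2] / np.sqrt(cov[2, 2])
    p_b = 2 * stats.t.sf(abs(t_b), dof)

    qa = np.minimum((ra - 1) * n_quantiles // n, n_quantiles - 1).astype(int)
    qb = np.minimum((rb - 1) * n_quantiles // n, n_quantiles - 1).astype(int)
    table = np.full((n_quantiles, n_quantiles), np.nan)
    for i in range(n_quantiles):
        for j in range(n_quantiles):
            sel = (qa == i) & (qb == j)
            if sel.any():
                table[i, j] = response[sel].mean()
    return {
        "slope_b": float(beta[2]),
        "t_b": float(t_b),
        "p_b": float(p_b),
        "quantile_table": table,
        "n": n,
    }
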