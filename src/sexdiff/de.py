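"""Per-gene weighted linear models with empirical-Bayes variance moderation.

The female-vs-male effect is estimated per gene by weighted least squares
on log2-CPM with covariates (batch, lane, birth weight, ancestry PCs),
residual variances are shrunk toward a scaled-F prior whose parameters
(d0, s0^2) are estimated by moment-matching the log residual variances,
and two-sided p-values from the moderated t (df = d0 + d) are adjusted
by Benjamini-Hochberg. Sex is coded with male as the reference, so the
coefficient is log2(female/male).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignMatrix",
    "GeneFit",
    "ModeratedFit",
    "build_design",
    "fit_gene_models",
    "ebayes_moderate",
    "bh_adjust",
    "de_table",
]


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    column_names: list[str]
    sample_ids: list[str]
    contrast: np.ndarray  # linear combination giving the female-vs-male effect

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        n, p = self.matrix.shape
        if len(self.column_names) != p or len(self.contrast) != p:
            raise ValueError("column_names/contrast length must match design columns")
        if np.linalg.matrix_rank(self.matrix) < p:
            raise ValueError("design matrix is rank deficient")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank — reported on rejection."""
    bad = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == rank:
            bad.append(names[j])
    return bad


def build_design(
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    reference_levels: dict[str, str] | None = None,
) -> DesignMatrix:
    """Treatment-coded design with an intercept and a female-vs-male
    contrast.

    ``sex`` is always included and coded against a male reference so the
    sex coefficient is log2(F/M). Categorical covariates (object/category
    dtype) get one indicator per non-reference level; numeric covariates
    enter as-is. Missing values among kept samples are rejected.
    """
    covariates = list(covariates or [])
    if "sex" not in covariates:
        covariates = ["sex"] + covariates
    reference_levels = dict(reference_levels or {})
    reference_levels.setdefault("sex", "male")
    cols = {"intercept": np.ones(len(metadata))}
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        col = metadata[cov]
        if col.isna().any():
            bad = col.index[col.isna()][0]
            raise ValueError(f"missing value for {cov!r} in sample {bad!r}")
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, col.unique()))
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found for {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}_{lev}"] = (col.astype(str) == lev).to_numpy(dtype=float)
        else:
            cols[cov] = col.to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    sex_cols = [c for c in names if c.startswith("sex_")]
    if len(sex_cols) != 1:
        raise ValueError("metadata must contain exactly two sex levels")
    contrast = np.zeros(len(names))
    contrast[names.index(sex_cols[0])] = 1.0
    return DesignMatrix(X, names, list(metadata.index), contrast)


@dataclass
class GeneFit:
    """Per-gene WLS output: coefficient on the contrast, its unscaled
    standard deviation, residual variance and residual df."""

    genes: pd.Index
    coef: np.ndarray
    stdev_unscaled: np.ndarray
    residual_var: np.ndarray
    residual_df: float
    avg_log_cpm: np.ndarray
    zero_variance: np.ndarray


def fit_gene_models(
    log_cpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: DesignMatrix,
) -> GeneFit:
    """Weighted least squares per gene, vectorized over genes.

    With unit weights this reduces exactly to OLS. Residual df is n - p
    for every gene.
    """
    X = design.matrix
    n, p = X.shape
    if list(log_cpm.columns) != list(design.sample_ids):
        raise ValueError("log_cpm columns must match design sample order")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    Y = log_cpm.to_numpy(dtype=float)
    if not np.isfinite(Y).all():
        raise ValueError("non-finite expression values")
    if weights is None:
        W = np.ones_like(Y)
    else:
        W = weights.loc[log_cpm.index, log_cpm.columns].to_numpy(dtype=float)
        if not np.isfinite(W).all() or (W <= 0).any():
            raise ValueError("weights must be finite and positive")
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    XtWy = np.einsum("ni,gn,gn->gi", X, W, Y)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])[:, :, 0]
    resid = Y - beta @ X.T
    rss = np.sum(W * resid**2, axis=1)
    s2 = rss / (n - p)
    XtWX_inv = np.linalg.inv(XtWX)
    c = design.contrast
    var_c = np.einsum("i,gij,j->g", c, XtWX_inv, c)
    coef = beta @ c
    return GeneFit(
        genes=log_cpm.index,
        coef=coef,
        stdev_unscaled=np.sqrt(var_c),
        residual_var=s2,
        residual_df=float(n - p),
        avg_log_cpm=Y.mean(axis=1),
        zero_variance=s2 <= 0,
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by guarded Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < tol:
            break
    return float(x)


@dataclass
class ModeratedFit:
    genes: pd.Index
    coef_log2fc: np.ndarray
    stdev_unscaled: np.ndarray
    residual_var_s2: np.ndarray
    residual_df_d: float
    prior_df_d0: float
    prior_var_s0sq: float
    posterior_var: np.ndarray
    moderated_t: np.ndarray
    p_value: np.ndarray
    avg_log_cpm: np.ndarray
    zero_variance: np.ndarray


def ebayes_moderate(fit: GeneFit, prior_df: float | None = None) -> ModeratedFit:
    """Shrink residual variances toward a scaled-F prior and form
    moderated t-statistics.

    (d0, s0^2) come from moment-matching the log residual variances: the
    excess of the empirical variance of log s^2 over trigamma(d/2) gives
    d0 via the trigamma inverse, and the mean gives s0^2 via digamma
    identities. Non-positive excess means the variances are consistent
    with a single value: d0 = inf, s0^2 is their plain mean, and every
    posterior variance equals s0^2.
    ``prior_df`` overrides the estimate (0 recovers the classical t).
    """
    if len(fit.genes) < 2:
        raise ValueError("need multiple genes to moderate variances")
    d = fit.residual_df
    s2 = np.asarray(fit.residual_var, dtype=float).copy()
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero")
    floor = np.finfo(float).eps
    s2 = np.maximum(s2, floor)
    if prior_df is None:
        z = np.log(s2)
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        emean = float(np.mean(e))
        n = len(e)
        evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(
            special.polygamma(1, d / 2.0)
        )
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s0sq = float(np.mean(s2))
    else:
        d0 = float(prior_df)
        if np.isinf(d0):
            s0sq = float(np.mean(s2))
        elif d0 > 0:
            z = np.log(s2)
            emean = float(np.mean(z - special.digamma(d / 2.0) + np.log(d / 2.0)))
            s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            s0sq = float(np.mean(s2))  # unused when d0 == 0
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
    else:
        post = (d0 * s0sq + d * s2) / (d0 + d)
    t = fit.coef / (fit.stdev_unscaled * np.sqrt(post))
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return ModeratedFit(
        genes=fit.genes,
        coef_log2fc=fit.coef,
        stdev_unscaled=fit.stdev_unscaled,
        residual_var_s2=s2,
        residual_df_d=d,
        prior_df_d0=d0,
        prior_var_s0sq=s0sq,
        posterior_var=post,
        moderated_t=t,
        p_value=p,
        avg_log_cpm=fit.avg_log_cpm,
        zero_variance=fit.zero_variance,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    mfit: ModeratedFit,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    subset: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE result table sorted by adjusted p, plus per-class significance
    counts.

    With ``subset`` the table is restricted to those genes and BH is
    recomputed over the subset only (for a subset analysis re-run from
    filtering onward, see ``SexDEModel.fit(gene_subset=...)``).
    """
    genes = list(mfit.genes)
    tab = pd.DataFrame(
        {
            "gene": genes,
            "logFC_F_vs_M": mfit.coef_log2fc,
            "AveLogCPM": mfit.avg_log_cpm,
            "t": mfit.moderated_t,
            "P.Value": mfit.p_value,
            "zero_variance": mfit.zero_variance,
        }
    ).set_index("gene")
    if subset is not None:
        keep = [g for g in genes if g in set(subset)]
        if not keep:
            raise ValueError("subset does not intersect the analyzed genes")
        tab = tab.loc[keep]
    tab["adj.P.Val"] = bh_adjust(tab["P.Value"].to_numpy())
    tab["chrom_class"] = annotation.loc[tab.index, "chrom_class"]
    tab["direction"] = np.where(tab["logFC_F_vs_M"] > 0, "female_up", "male_up")
    tab["significant"] = tab["adj.P.Val"] <= alpha
    tab = tab.sort_values("adj.P.Val", kind="mergesort")
    sig = tab[tab["significant"]]
    counts = (
        sig.groupby(["chrom_class", "direction"], observed=False)
        .size()
        .rename("n_significant")
        .reset_index()
    )
    return tab, counts
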