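"""Count-matrix containers and the normalization / transformation core.

Implements the expression side of a limma/voom-style workflow: technical
replicate summing, CPM/FPKM, expression filtering, TMM library-size
normalization, prior-augmented log2-CPM, mean-variance precision weights,
leading-logFC multidimensional scaling and batch-effect removal for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CountMatrix",
    "NormalizedExpression",
    "sum_technical_replicates",
    "compute_cpm",
    "compute_fpkm",
    "filter_expressed",
    "tmm_normalize",
    "log_cpm_transform",
    "precision_weights",
    "leading_logfc_mds",
    "remove_batch_effect",
]

CHROM_CLASSES = ("autosome", "mito", "X", "Y", "X_PAR")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with linked annotation and metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, genes in rows, samples in
        columns.
    gene_annotation
        Per-gene table indexed like ``counts.index`` with at least
        ``chrom_class`` (one of autosome/mito/X/Y/X_PAR), ``length_bp`` and
        ``gametolog_partner`` (gene id or NA).
    sample_metadata
        Per-sample table indexed like ``counts.columns`` with at least
        ``sex`` and ``replicate_group``; typically also batch, lane,
        birth_weight_kg and ancestry PCs.
    """

    counts: pd.DataFrame
    gene_annotation: pd.DataFrame
    sample_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in counts")
        if not self.counts.index.isin(self.gene_annotation.index).all():
            missing = self.counts.index.difference(self.gene_annotation.index)
            raise ValueError(f"annotation missing for genes: {list(missing[:5])}")
        if not self.counts.columns.isin(self.sample_metadata.index).all():
            missing = self.counts.columns.difference(self.sample_metadata.index)
            raise ValueError(f"metadata missing for samples: {list(missing[:5])}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        # align side tables to the matrix
        self.gene_annotation = self.gene_annotation.loc[self.counts.index]
        self.sample_metadata = self.sample_metadata.loc[self.counts.columns]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        genes = [g for g in self.counts.index if g in set(genes)]
        return CountMatrix(
            self.counts.loc[genes],
            self.gene_annotation.loc[genes],
            self.sample_metadata.copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        samples = [s for s in self.counts.columns if s in set(samples)]
        return CountMatrix(
            self.counts[samples],
            self.gene_annotation.copy(),
            self.sample_metadata.loc[samples],
        )

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass
class NormalizedExpression:
    """TMM factors, log2-CPM and per-observation precision weights."""

    tmm_factor: pd.Series
    effective_lib_size: pd.Series
    log_cpm: pd.DataFrame
    precision_weight: pd.DataFrame | None = None
    prior_count: float = 0.25
    mean_var_trend: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        gm = np.exp(np.mean(np.log(self.tmm_factor.to_numpy())))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")
        if not np.isfinite(self.log_cpm.to_numpy()).all():
            raise ValueError("log_cpm contains non-finite values")


def sum_technical_replicates(cm: CountMatrix) -> CountMatrix:
    """Sum technical replicate columns within each ``replicate_group``.

    Metadata within a group must agree except for ``lane``, which is
    recorded as the comma-joined set of contributing lanes. Total counts
    are conserved.
    """
    meta = cm.sample_metadata
    if meta["replicate_group"].isna().any():
        raise ValueError("replicate_group must be set for every sample")
    groups = meta.groupby("replicate_group", sort=False)
    check_cols = [
        c
        for c in meta.columns
        if c not in ("lane", "replicate_group", "target_lib_size")
    ]
    rows = []
    summed = {}
    for gid, sub in groups:
        for col in check_cols:
            if sub[col].nunique(dropna=False) > 1:
                raise ValueError(
                    f"replicate group {gid!r} has conflicting values for {col!r}"
                )
        row = sub.iloc[0].copy()
        if "lane" in sub:
            row["lane"] = ",".join(sorted(map(str, sub["lane"].unique())))
        if "target_lib_size" in sub:
            row["target_lib_size"] = int(sub["target_lib_size"].sum())
        row.name = gid
        rows.append(row)
        summed[gid] = cm.counts[sub.index].sum(axis=1)
    new_counts = pd.DataFrame(summed)
    new_meta = pd.DataFrame(rows)
    new_meta["replicate_group"] = new_meta.index
    return CountMatrix(new_counts, cm.gene_annotation.copy(), new_meta)


def _counts_frame(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return cm.counts if isinstance(cm, CountMatrix) else cm


def compute_cpm(
    cm: CountMatrix | pd.DataFrame,
    prior_count: float = 0.0,
    lib_size: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million. With ``prior_count`` 0 each column sums to 1e6.

    A positive prior is scaled per sample by relative library size
    (``prior * lib_j / mean(lib)``) and the denominator augmented by twice
    the sample prior, so prior-augmented CPM stays a proper rate.
    """
    counts = _counts_frame(cm)
    lib = counts.sum(axis=0) if lib_size is None else lib_size.loc[counts.columns]
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero-depth sample: {bad!r}")
    if prior_count == 0:
        return counts / lib * 1e6
    pr = prior_count * lib / lib.mean()
    return (counts + pr) / (lib + 2 * pr) * 1e6


def compute_fpkm(cm: CountMatrix, lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: count / (length_kb * depth_M)."""
    lengths = cm.gene_annotation["length_bp"]
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][0]
        raise ValueError(f"missing or non-positive gene length: {bad!r}")
    lib = cm.lib_size if lib_size is None else lib_size.loc[cm.counts.columns]
    return cm.counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def filter_expressed(
    cm: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    fpkm_threshold: float = 1.0,
    rule: Literal["all_of_any_group", "mean_of_any_group"] = "all_of_any_group",
) -> tuple[CountMatrix, list[str]]:
    """Keep genes with FPKM above threshold in every sample of (or on
    average within) at least one group.

    The default all-samples-of-a-group rule keeps a gene expressed in all
    samples of one sex even when absent from the other, which is how
    sex-limited (e.g. Y-linked) genes survive the filter.
    """
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"empty group {name!r}")
    fpkm = compute_fpkm(cm)
    keep = pd.Series(False, index=cm.counts.index)
    for members in groups.values():
        sub = fpkm[list(members)]
        if rule == "all_of_any_group":
            keep |= (sub > fpkm_threshold).all(axis=1)
        elif rule == "mean_of_any_group":
            keep |= sub.mean(axis=1) > fpkm_threshold
        else:
            raise ValueError(f"unknown rule {rule!r}")
    kept = list(cm.counts.index[keep])
    return cm.subset_genes(kept), kept


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Two-sample TMM factor: doubly trimmed, precision-weighted mean of
    M-values of obs against ref; genes with a zero in either sample are
    excluded, weights come from the binomial delta-method variance."""
    pos = (obs > 0) & (ref > 0)
    if pos.sum() == 0:
        return 1.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    v = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(
    cm: CountMatrix | pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> tuple[pd.Series, pd.Series]:
    """Trimmed mean of M-values normalization.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile; factors are rescaled to geometric mean 1 and
    ``effective_lib_size = depth * factor``.
    """
    counts = _counts_frame(cm)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero-depth sample")
    x = counts.to_numpy(dtype=float)
    libv = lib.to_numpy(dtype=float)
    uq = np.quantile(x / libv, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(
                x[:, j], x[:, ref_idx], libv[j], libv[ref_idx], logratio_trim, abs_trim
            )
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    f = pd.Series(factors, index=counts.columns, name="tmm_factor")
    eff = pd.Series(libv * factors, index=counts.columns, name="effective_lib_size")
    return f, eff


def log_cpm_transform(
    cm: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.25,
    literal_prior: bool = False,
) -> pd.DataFrame:
    """log2 CPM with a prior count so zeros map to a finite value.

    The prior is added to counts (scaled per sample by relative effective
    library size) before forming CPM. ``literal_prior`` instead computes
    ``log2(CPM + prior/L)`` — adding the prior on the CPM scale after the
    fact — for comparison; with library sizes in the tens of millions that
    prior is negligible (~1e-8 CPM) and zero counts map to an extreme
    outlier value near log2(prior/L), so it is not usable downstream.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    counts = _counts_frame(cm)
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    if literal_prior:
        cpm = counts / lib * 1e6
        return np.log2(cpm + prior_count / lib)
    pr = prior_count * lib / lib.mean()
    return np.log2((counts + pr) / (lib + 2 * pr) * 1e6)


def precision_weights(
    log_cpm: pd.DataFrame,
    design: np.ndarray,
    span: float = 0.5,
    eff_lib: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-variance precision weights for weighted linear modelling.

    Each gene is first fit unweighted against ``design``; the square root
    of the residual standard deviation is smoothed (lowess, ``span``)
    against average log2 count, and every observation's weight is the
    inverse fourth power of the trend evaluated at its fitted log2 count.

    Returns the weight matrix and the lowess trend as an (x, y) array.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if log_cpm.shape[1] != n:
        raise ValueError("design rows must match samples")
    if n - p < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    Y = log_cpm.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    sigma = np.sqrt(np.sum(resid**2, axis=1) / (n - p))
    if eff_lib is not None:
        shift = np.log2(eff_lib.loc[log_cpm.columns].to_numpy(dtype=float) + 1.0) - np.log2(1e6)
    else:
        shift = np.zeros(n)
    sx = Y.mean(axis=1) + shift.mean()
    sy = np.sqrt(sigma)
    # guard all-zero-residual genes so the trend stays finite
    ok = np.isfinite(sy)
    trend = sm.nonparametric.lowess(sy[ok], sx[ok], frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    fitted_logcount = fitted + shift[None, :]
    w = np.interp(fitted_logcount, tx, ty)  # clamped at the range ends
    w = np.maximum(w, 1e-6) ** -4
    weights = pd.DataFrame(w, index=log_cpm.index, columns=log_cpm.columns)
    return weights, trend


def leading_logfc_mds(
    log_cpm: pd.DataFrame,
    n_top: int = 500,
    gene_selection: Literal["common", "pairwise"] = "common",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MDS where distance approximates the typical leading log2 fold change.

    ``common`` selects the ``n_top`` genes with the largest standard
    deviation across all samples once; ``pairwise`` picks, per sample
    pair, the genes with the largest absolute difference. Distance is the
    root-mean-square log2 difference over the selected genes; coordinates
    come from classical metric scaling (double-centred squared distances),
    so they are unique only up to sign — the first coordinate of each
    dimension is fixed non-negative.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    Y = log_cpm.to_numpy(dtype=float)
    g, n = Y.shape
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    k = min(n_top, g)
    D = np.zeros((n, n))
    if gene_selection == "common":
        sd = Y.std(axis=1, ddof=1)
        top = np.argsort(sd)[::-1][:k]
        sub = Y[top]
        for i in range(n):
            for j in range(i + 1, n):
                d = np.sqrt(np.mean((sub[:, i] - sub[:, j]) ** 2))
                D[i, j] = D[j, i] = d
    elif gene_selection == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                diff = np.abs(Y[:, i] - Y[:, j])
                top = np.sort(diff)[::-1][:k]
                d = np.sqrt(np.mean(top**2))
                D[i, j] = D[j, i] = d
    else:
        raise ValueError(f"unknown gene_selection {gene_selection!r}")
    # classical scaling
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, 2))
    for dim in range(2):
        lam = max(evals[dim], 0.0)
        v = evecs[:, dim] * np.sqrt(lam)
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if len(nz) and v[nz[0]] < 0:
            v = -v
        coords[:, dim] = v
    cdf = pd.DataFrame(coords, index=log_cpm.columns, columns=["dim1", "dim2"])
    ddf = pd.DataFrame(D, index=log_cpm.columns, columns=log_cpm.columns)
    return cdf, ddf


def remove_batch_effect(
    log_cpm: pd.DataFrame,
    batch: pd.Series | Sequence,
    retained_design: np.ndarray | None = None,
) -> pd.DataFrame:
    """Subtract fitted batch terms from log-CPM, for visualization only.

    Batch is coded with sum-to-zero contrasts so removal does not shift
    the overall mean; the retained design (e.g. intercept + sex) is kept
    in the fit and its contribution is left untouched.
    """
    batch = pd.Series(np.asarray(batch), index=log_cpm.columns)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return log_cpm.copy()
    n = log_cpm.shape[1]
    if retained_design is None:
        X0 = np.ones((n, 1))
    else:
        X0 = np.asarray(retained_design, dtype=float)
    # sum-to-zero contrasts: level i -> e_i (i < L-1), last level -> -1s
    L = len(levels)
    C = np.zeros((n, L - 1))
    for j, s in enumerate(log_cpm.columns):
        i = levels.index(batch[s])
        if i < L - 1:
            C[j, i] = 1.0
        else:
            C[j, :] = -1.0
    X = np.hstack([X0, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with the retained design")
    Y = log_cpm.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    batch_part = (C @ beta[X0.shape[1] :, :]).T
    return pd.DataFrame(
        Y - batch_part, index=log_cpm.index, columns=log_cpm.columns
    )
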