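"""Model/Results front end for the sex-differential-expression workflow.

``SexDEModel`` holds the data and modelling choices; ``fit()`` runs the
whole pipeline — technical-replicate summing, FPKM expression filtering,
TMM normalization, prior-augmented log2-CPM, mean-variance precision
weights, per-gene weighted least squares, empirical-Bayes moderation and
BH adjustment — and returns a ``SexDEResults`` carrying the estimates,
their moderated uncertainties and a summary table. Subset analyses
(e.g. an innate-immune gene list) re-run the pipeline from filtering
onward on the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de as _de
from . import expression as _expr
from .expression import CountMatrix, NormalizedExpression

__all__ = ["SexDEModel", "SexDEResults"]

DEFAULT_COVARIATES = ["sex"]


class SexDEModel:
    """Female-vs-male differential expression on a count matrix.

    Parameters
    ----------
    data
        A :class:`CountMatrix`. Technical replicates (same
        ``replicate_group``) are summed before modelling.
    covariates
        Metadata columns entering the linear model besides sex (e.g.
        ``["batch", "lane", "birth_weight_kg", "ancestry_pc1",
        "ancestry_pc2"]``). Sex is always included, male as reference.
    fpkm_threshold, filter_rule
        Expression filter: keep genes above threshold in every sample of
        at least one sex (default) or above the group mean.
    prior_count
        Prior count for the log2-CPM transform (default 0.25).
    """

    def __init__(
        self,
        data: CountMatrix,
        covariates: list[str] | None = None,
        fpkm_threshold: float = 1.0,
        filter_rule: str = "all_of_any_group",
        prior_count: float = 0.25,
        voom_span: float = 0.5,
        sum_replicates: bool = True,
    ) -> None:
        self.data = data
        self.covariates = list(covariates or [])
        self.fpkm_threshold = fpkm_threshold
        self.filter_rule = filter_rule
        self.prior_count = prior_count
        self.voom_span = voom_span
        self.sum_replicates = sum_replicates

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        gene_annotation: pd.DataFrame,
        sample_metadata: pd.DataFrame,
        **kwargs,
    ) -> "SexDEModel":
        return cls(CountMatrix(counts, gene_annotation, sample_metadata), **kwargs)

    # -- pipeline pieces -------------------------------------------------

    def _collapsed(self) -> CountMatrix:
        cm = self.data
        if self.sum_replicates and "replicate_group" in cm.sample_metadata:
            if cm.sample_metadata["replicate_group"].nunique() < cm.n_samples:
                cm = _expr.sum_technical_replicates(cm)
        return cm

    def _sex_groups(self, cm: CountMatrix) -> dict[str, list[str]]:
        meta = cm.sample_metadata
        return {
            sex: list(meta.index[meta["sex"] == sex])
            for sex in ("female", "male")
            if (meta["sex"] == sex).any()
        }

    def fit(self, alpha: float = 0.05, gene_subset: list[str] | None = None) -> "SexDEResults":
        """Run the pipeline and return results.

        ``gene_subset`` restricts the analysis to the named genes before
        filtering, so normalization, weights and BH adjustment are all
        recomputed within the subset.
        """
        cm = self._collapsed()
        if gene_subset is not None:
            inter = [g for g in cm.counts.index if g in set(gene_subset)]
            if not inter:
                raise ValueError("gene subset does not intersect the count matrix")
            cm = cm.subset_genes(inter)
        groups = self._sex_groups(cm)
        filtered, kept = _expr.filter_expressed(
            cm, groups, self.fpkm_threshold, self.filter_rule
        )
        factors, eff_lib = _expr.tmm_normalize(filtered)
        log_cpm = _expr.log_cpm_transform(filtered, factors, self.prior_count)
        design = _de.build_design(filtered.sample_metadata, self.covariates)
        weights, trend = _expr.precision_weights(
            log_cpm, design.matrix, span=self.voom_span, eff_lib=eff_lib
        )
        norm = NormalizedExpression(
            tmm_factor=factors,
            effective_lib_size=eff_lib,
            log_cpm=log_cpm,
            precision_weight=weights,
            prior_count=self.prior_count,
            mean_var_trend=trend,
        )
        gfit = _de.fit_gene_models(log_cpm, weights, design)
        mfit = _de.ebayes_moderate(gfit)
        table, class_counts = _de.de_table(mfit, filtered.gene_annotation, alpha=alpha)
        return SexDEResults(
            model=self,
            count_matrix=filtered,
            kept_genes=kept,
            norm=norm,
            design=design,
            mfit=mfit,
            table=table,
            class_counts=class_counts,
            alpha=alpha,
        )


@dataclass
class SexDEResults:
    """Fitted sex-DE results: per-gene log2(F/M), moderated t, BH-adjusted
    p-values, normalization diagnostics and the design used."""

    model: SexDEModel
    count_matrix: CountMatrix
    kept_genes: list[str]
    norm: NormalizedExpression
    design: _de.DesignMatrix
    mfit: _de.ModeratedFit
    table: pd.DataFrame
    class_counts: pd.DataFrame
    alpha: float = 0.05
    _mds_cache: dict = field(default_factory=dict, repr=False)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def mds(self, n_top: int = 500, gene_selection: str = "common", remove_batch: bool = False):
        """Leading-logFC MDS coordinates of the modelled samples."""
        log_cpm = self.norm.log_cpm
        if remove_batch and "batch" in self.count_matrix.sample_metadata:
            log_cpm = _expr.remove_batch_effect(
                log_cpm, self.count_matrix.sample_metadata["batch"]
            )
        coords, _ = _expr.leading_logfc_mds(log_cpm, n_top, gene_selection)
        return coords

    def summary(self) -> str:
        t = self.table
        sig = self.significant
        lines = [
            "Sex-differential expression (female vs male)",
            "=" * 46,
            f"samples:            {self.count_matrix.n_samples}"
            f" ({(self.count_matrix.sample_metadata['sex'] == 'female').sum()} F /"
            f" {(self.count_matrix.sample_metadata['sex'] == 'male').sum()} M)",
            f"genes analyzed:     {len(t)}",
            f"prior df (d0):      {self.mfit.prior_df_d0:.4g}",
            f"prior var (s0^2):   {self.mfit.prior_var_s0sq:.4g}",
            f"significant (BH <= {self.alpha:g}): {len(sig)}"
            f" ({(sig['direction'] == 'female_up').sum()} female-up /"
            f" {(sig['direction'] == 'male_up').sum()} male-up)",
        ]
        if len(self.class_counts):
            lines.append("by chromosome class:")
            for r in self.class_counts.itertuples(index=False):
                lines.append(f"  {r.chrom_class:<9} {r.direction:<10} {r.n_significant}")
        lines.append("top genes:")
        head = t.head(min(5, len(t)))
        for g, row in head.iterrows():
            lines.append(
                f"  {g:<12} logFC={row['logFC_F_vs_M']:+.3f}"
                f"  t={row['t']:+.2f}  adj.p={row['adj.P.Val']:.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        colors = {"autosome": "purple", "mito": "purple", "X": "green", "X_PAR": "green", "Y": "orange"}
        base = ~t["significant"]
        ax.scatter(t.loc[base, "logFC_F_vs_M"], -np.log10(t.loc[base, "P.Value"]),
                   s=6, c="lightgray", label=None)
        for cls, col in colors.items():
            m = t["significant"] & (t["chrom_class"] == cls)
            if m.any():
                ax.scatter(t.loc[m, "logFC_F_vs_M"], -np.log10(t.loc[m, "P.Value"]),
                           s=10, c=col, label=cls)
        ax.set_xlabel("log2(female / male)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax
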