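"""Cross-tissue correlation of log2 female-to-male expression ratios.

Placenta F/M ratios are correlated against each adult tissue's ratios
within gene classes: all expressed genes, all minus the sex-DE set, the
sex-DE set, and its autosomal / X-linked / Y-linked subdivisions (mito
grouped with autosomal). Correlations are Pearson by default with
p-values from the t-transform of r, BH-adjusted per class column across
tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "GeneClassSets",
    "compute_fm_ratios",
    "partition_gene_classes",
    "correlate_ratios",
]

CLASS_ORDER = ["all", "exclude_sd", "all_sd", "autosomal_sd", "x_linked_sd", "y_linked_sd"]


def compute_fm_ratios(
    mean_tpm_by_sex: pd.DataFrame,
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2((F + eps) / (M + eps)) per gene per tissue.

    Input is a long table with columns tissue, gene, mean_tpm_female,
    mean_tpm_male. Genes with both sex means zero are dropped and
    returned in a separate table with a reason.
    """
    df = mean_tpm_by_sex.copy()
    for col in ("tissue", "gene", "mean_tpm_female", "mean_tpm_male"):
        if col not in df.columns:
            raise ValueError(f"mean TPM table is missing column {col!r}")
    if (df["mean_tpm_female"] < 0).any() or (df["mean_tpm_male"] < 0).any():
        raise ValueError("negative TPM values")
    both_zero = (df["mean_tpm_female"] == 0) & (df["mean_tpm_male"] == 0)
    dropped = df.loc[both_zero, ["tissue", "gene"]].copy()
    dropped["reason"] = "zero_in_both_sexes"
    df = df.loc[~both_zero].copy()
    df["log2_fm_ratio"] = np.log2(
        (df["mean_tpm_female"] + epsilon) / (df["mean_tpm_male"] + epsilon)
    )
    return df, dropped


@dataclass
class GeneClassSets:
    all: set
    exclude_sd: set
    all_sd: set
    autosomal_sd: set
    x_linked_sd: set
    y_linked_sd: set

    def __post_init__(self) -> None:
        union = self.autosomal_sd | self.x_linked_sd | self.y_linked_sd
        if union != self.all_sd:
            raise ValueError("sex-DE subclasses must partition all_sd")
        if self.exclude_sd != self.all - self.all_sd:
            raise ValueError("exclude_sd must equal all minus all_sd")

    def as_dict(self) -> dict[str, set]:
        return {name: getattr(self, name) for name in CLASS_ORDER}


def partition_gene_classes(
    de_tables: Sequence[pd.DataFrame],
    annotation: pd.DataFrame,
    expressed_genes: Iterable[str],
    ratio_genes: Iterable[str] | None = None,
) -> GeneClassSets:
    """Build the gene-class sets used for cross-tissue correlation.

    ``all`` is the expressed genes restricted to those with ratio data
    (``ratio_genes``, e.g. genes present in every compared tissue);
    ``all_sd`` is the union of significant genes across the provided DE
    tables intersected with ``all``, split by chromosome class with mito
    counted as autosomal and X_PAR as X-linked.
    """
    all_genes = set(expressed_genes)
    if ratio_genes is not None:
        all_genes &= set(ratio_genes)
    sd: set = set()
    for tab in de_tables:
        sd |= set(tab.index[tab["significant"]])
    sd &= all_genes
    cls = annotation["chrom_class"]
    auto = {g for g in sd if cls.get(g) in ("autosome", "mito")}
    x = {g for g in sd if cls.get(g) in ("X", "X_PAR")}
    y = {g for g in sd if cls.get(g) == "Y"}
    return GeneClassSets(
        all=all_genes,
        exclude_sd=all_genes - sd,
        all_sd=sd,
        autosomal_sd=auto,
        x_linked_sd=x,
        y_linked_sd=y,
    )


def correlate_ratios(
    placenta_ratios: pd.DataFrame,
    tissue_panel: pd.DataFrame,
    classes: GeneClassSets,
    adjust: str = "bh",
    method: str = "pearson",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (tissue, gene class) correlation of log2 F/M ratios.

    ``placenta_ratios`` and ``tissue_panel`` are ratio tables from
    :func:`compute_fm_ratios` (the panel with one block per tissue).
    Cells with fewer than 3 shared finite-ratio genes are reported as
    not computed. BH adjustment runs within each class column across
    tissues (``adjust="global"`` pools all cells instead).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    plac = placenta_ratios.set_index("gene")["log2_fm_ratio"]
    plac = plac[np.isfinite(plac)]
    rows = []
    any_shared = False
    for tissue, block in tissue_panel.groupby("tissue", sort=True):
        tiss = block.set_index("gene")["log2_fm_ratio"]
        tiss = tiss[np.isfinite(tiss)]
        shared_all = plac.index.intersection(tiss.index)
        if len(shared_all):
            any_shared = True
        for cls_name, genes in classes.as_dict().items():
            shared = [g for g in shared_all if g in genes]
            if len(shared) < 3:
                rows.append(
                    {
                        "tissue": tissue,
                        "gene_class": cls_name,
                        "n_genes": len(shared),
                        "r": np.nan,
                        "p": np.nan,
                        "computed": False,
                    }
                )
                continue
            x = plac.loc[shared].to_numpy()
            y = tiss.loc[shared].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                # constant ratios carry no correlation information
                rows.append(
                    {
                        "tissue": tissue,
                        "gene_class": cls_name,
                        "n_genes": len(shared),
                        "r": np.nan,
                        "p": np.nan,
                        "computed": False,
                    }
                )
                continue
            if method == "pearson":
                res = stats.pearsonr(x, y)
            else:
                res = stats.spearmanr(x, y)
            rows.append(
                {
                    "tissue": tissue,
                    "gene_class": cls_name,
                    "n_genes": len(shared),
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                    "computed": True,
                }
            )
    if not any_shared:
        raise ValueError("no genes shared between placenta ratios and the panel")
    out = pd.DataFrame(rows)
    out["adj_p"] = np.nan
    if adjust == "bh":
        for cls_name in CLASS_ORDER:
            m = (out["gene_class"] == cls_name) & out["computed"]
            if m.any():
                out.loc[m, "adj_p"] = bh_adjust(out.loc[m, "p"].to_numpy())
    elif adjust == "global":
        m = out["computed"]
        out.loc[m, "adj_p"] = bh_adjust(out.loc[m, "p"].to_numpy())
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["significant"] = out["adj_p"] <= alpha
    return out
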