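"""X-Y gametolog expression analysis.

Gametologs are X-Y gene pairs retaining functional copies on both sex
chromosomes. Comparing female X-linked expression to male X-linked
expression alone can misstate the sex difference when the Y copy is also
expressed, so each pair is tested twice: X-only, and with the male X and
Y CPM summed under the X-linked label. The classifier reports whether
the inference is unchanged, loses significance, gains significance, or
flips direction when the Y copy is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, compute_cpm, compute_fpkm, tmm_normalize

__all__ = [
    "GametologPair",
    "load_default_pairs",
    "rank_sum_test",
    "sum_gametolog_expression",
    "classify_gametolog_outcome",
    "run_gametolog_analysis",
]


@dataclass(frozen=True)
class GametologPair:
    x_gene: str
    y_gene: str


def load_default_pairs() -> list[GametologPair]:
    """The packaged X-Y pair registry (replaceable by the user)."""
    with resources.files("sexdiff.data").joinpath("gametolog_pairs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [GametologPair(r.x_gene, r.y_gene) for r in df.itertuples()]


def read_pairs(path) -> list[GametologPair]:
    df = pd.read_csv(path, sep="\t")
    return [GametologPair(r.x_gene, r.y_gene) for r in df.itertuples()]


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: Literal["exact", "normal_approx_cc", "auto"] = "auto",
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value and direction of median shift.

    ``auto`` uses exact enumeration when both groups have <= 10
    observations and there are no ties, else the normal approximation
    with tie and continuity corrections. Direction is ``a_up`` /
    ``b_up`` / ``none`` from the group medians.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if method == "auto":
        method = (
            "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "normal_approx_cc"
        )
    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif method == "normal_approx_cc":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    med_a, med_b = np.median(a), np.median(b)
    if med_a > med_b:
        direction = "a_up"
    elif med_b > med_a:
        direction = "b_up"
    else:
        direction = "none"
    return float(min(res.pvalue, 1.0)), direction


def welch_t_test(group_a, group_b) -> tuple[float, str]:
    """Welch two-sample t-test, available for sensitivity comparison."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    if a.mean() > b.mean():
        direction = "a_up"
    elif b.mean() > a.mean():
        direction = "b_up"
    else:
        direction = "none"
    return float(res.pvalue), direction


def sum_gametolog_expression(
    cpm: pd.DataFrame,
    pairs: Sequence[GametologPair],
    male_samples: Sequence[str],
    female_samples: Sequence[str],
) -> tuple[list[dict], list[str]]:
    """Per-pair expression series: female X, male X, male Y, male X+Y.

    Female values are never summed; Y CPM observed in female samples is
    reported in a diagnostic field. Pairs with a missing gene are
    skipped with a warning record.
    """
    records, warnings = [], []
    males = list(male_samples)
    females = list(female_samples)
    for pair in pairs:
        if pair.x_gene not in cpm.index or pair.y_gene not in cpm.index:
            warnings.append(
                f"pair {pair.x_gene}/{pair.y_gene} skipped: gene missing from matrix"
            )
            continue
        fx = cpm.loc[pair.x_gene, females].to_numpy(dtype=float)
        mx = cpm.loc[pair.x_gene, males].to_numpy(dtype=float)
        my = cpm.loc[pair.y_gene, males].to_numpy(dtype=float)
        fy = cpm.loc[pair.y_gene, females].to_numpy(dtype=float)
        records.append(
            {
                "pair": pair,
                "female_x_cpm": fx,
                "male_x_cpm": mx,
                "male_y_cpm": my,
                "male_sum_cpm": mx + my,
                "female_y_cpm_total": float(fy.sum()),
            }
        )
    return records, warnings


def classify_gametolog_outcome(
    p_x_only: float,
    dir_x_only: str,
    p_summed: float,
    dir_summed: str,
    alpha: float = 0.05,
) -> str:
    """Outcome of adding the Y copy: unchanged / lost_significance /
    gained_significance / flipped_direction."""
    sig_x = p_x_only < alpha
    sig_sum = p_summed < alpha
    if sig_x and sig_sum and dir_x_only != dir_summed:
        return "flipped_direction"
    if sig_x and not sig_sum:
        return "lost_significance"
    if sig_sum and not sig_x:
        return "gained_significance"
    return "unchanged"


_DIR_LABEL = {"a_up": "female_up", "b_up": "male_up", "none": "none"}


def run_gametolog_analysis(
    cm: CountMatrix,
    pairs: Sequence[GametologPair] | None = None,
    alpha: float = 0.05,
    fpkm_threshold: float = 1.0,
    test: Literal["wilcoxon", "ttest"] = "wilcoxon",
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Full gametolog comparison table on a count matrix.

    CPM is prior-free, on TMM effective library sizes by default. A pair
    passes the expression filter when the X member's FPKM exceeds the
    threshold in all female samples, or the male X+Y summed FPKM exceeds
    it in all male samples. Both tests (X-only and summed) run per
    retained pair; p-values are reported unadjusted for the outcome call
    with a BH column across pairs for reference.
    """
    if pairs is None:
        pairs = load_default_pairs()
    if not list(pairs):
        raise ValueError("pairs list is empty")
    meta = cm.sample_metadata
    females = list(meta.index[meta["sex"] == "female"])
    males = list(meta.index[meta["sex"] == "male"])
    if len(females) < 2 or len(males) < 2:
        raise ValueError("need at least 2 samples of each sex")
    if use_tmm and cm.n_samples >= 2:
        _, eff_lib = tmm_normalize(cm)
    else:
        eff_lib = cm.lib_size.astype(float)
    cpm = compute_cpm(cm, prior_count=0.0, lib_size=eff_lib)
    fpkm = compute_fpkm(cm, lib_size=eff_lib)
    records, warnings = sum_gametolog_expression(cpm, pairs, males, females)
    test_fn = rank_sum_test if test == "wilcoxon" else welch_t_test
    rows = []
    for rec in records:
        pair: GametologPair = rec["pair"]
        x_f = fpkm.loc[pair.x_gene, females]
        m_sum = fpkm.loc[pair.x_gene, males] + fpkm.loc[pair.y_gene, males]
        expressed = bool((x_f > fpkm_threshold).all() or (m_sum > fpkm_threshold).all())
        if not expressed:
            continue
        p_x, d_x = test_fn(rec["female_x_cpm"], rec["male_x_cpm"])
        p_s, d_s = test_fn(rec["female_x_cpm"], rec["male_sum_cpm"])
        outcome = classify_gametolog_outcome(
            p_x, _DIR_LABEL[d_x], p_s, _DIR_LABEL[d_s], alpha
        )
        rows.append(
            {
                "x_gene": pair.x_gene,
                "y_gene": pair.y_gene,
                "mean_female_x_cpm": float(np.mean(rec["female_x_cpm"])),
                "mean_male_x_cpm": float(np.mean(rec["male_x_cpm"])),
                "mean_male_y_cpm": float(np.mean(rec["male_y_cpm"])),
                "mean_male_sum_cpm": float(np.mean(rec["male_sum_cpm"])),
                "female_y_cpm_total": rec["female_y_cpm_total"],
                "p_x_only": p_x,
                "direction_x_only": _DIR_LABEL[d_x],
                "p_summed": p_s,
                "direction_summed": _DIR_LABEL[d_s],
                "outcome": outcome,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "x_gene",
            "y_gene",
            "mean_female_x_cpm",
            "mean_male_x_cpm",
            "mean_male_y_cpm",
            "mean_male_sum_cpm",
            "female_y_cpm_total",
            "p_x_only",
            "direction_x_only",
            "p_summed",
            "direction_summed",
            "outcome",
        ],
    )
    if len(out):
        from .de import bh_adjust

        out["adj_p_x_only"] = bh_adjust(out["p_x_only"].to_numpy())
        out["adj_p_summed"] = bh_adjust(out["p_summed"].to_numpy())
    out.attrs["warnings"] = warnings
    if not len(out):
        out.attrs["notice"] = "no gametolog pair passed the expression filter"
    return out
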