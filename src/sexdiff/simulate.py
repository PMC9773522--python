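"""Synthetic bulk RNA-seq generator with known sex-difference ground truth.

Emulates the structure of a two-sex placenta cohort: negative-binomial
counts, XIST-like female marker, Y-linked male-only genes (including the
five canonical Y markers), X-inactivation escapers, X-Y gametolog pairs
with a plantable inference outcome, autosomal null and sex-DE genes,
batch/lane effects, technical replicates, and a multi-tissue panel that
shares sex-linked effects but re-draws autosomal sex effects per tissue.

Defaults mirror the study conditions the package targets: 27 XX / 23 XY
samples in two batches with two technical replicates per placenta,
library sizes around 35M reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "Y_MARKERS",
    "XIST",
    "GametologSpec",
    "SimulationDesign",
    "simulate_experiment",
    "simulate_qc_profiles",
    "simulate_tissue_panel",
]

Y_MARKERS = ("EIF1AY", "KDM5D", "UTY", "DDX3Y", "RPS4Y1")
XIST = "XIST"

# marker means (CPM): unambiguous complement calls by construction
XIST_CPM_FEMALE = 100.0
XIST_CPM_MALE = 0.1
Y_MARKER_CPM_MALE = 20.0

GAMETOLOG_OUTCOMES = ("unchanged", "lost", "flipped", "gained")


@dataclass(frozen=True)
class GametologSpec:
    """A plantable X-Y pair.

    ``y_fraction_of_x`` sets male Y CPM as a fraction of male X CPM; the
    planted outcome fixes the female X mean relative to the male series:

    - unchanged: female X = 2 x male (X+Y) — female-biased either way
    - lost:      female X = male X + male Y — bias disappears on summing
    - flipped:   female X = 2 x male X — needs y_fraction > 3 to reverse
    - gained:    female X = male X — bias appears only on summing
    """

    x_name: str
    y_name: str
    x_base_log2cpm: float = 4.0
    y_fraction_of_x: float = 1.0
    planted_outcome: str = "unchanged"


@dataclass
class SimulationDesign:
    n_female: int = 27
    n_male: int = 23
    n_genes_autosomal_null: int = 5000
    n_genes_autosomal_sexde: int = 0
    n_genes_x_escape: int = 28
    n_genes_y_linked: int = 18
    gametolog_pairs: Sequence[GametologSpec] = field(default_factory=tuple)
    effect_size_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (25_000_000, 45_000_000)
    n_batches: int = 2
    batch_effect_sd: float = 0.25
    replicate_count_per_sample: int = 2
    seed: int = 0

    def validate(self) -> None:
        for fld in (
            "n_female",
            "n_male",
            "n_genes_autosomal_null",
            "n_genes_autosomal_sexde",
            "n_genes_x_escape",
            "n_genes_y_linked",
            "n_batches",
            "replicate_count_per_sample",
        ):
            v = getattr(self, fld)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"invalid design field {fld!r}: {v!r}")
        if self.n_female + self.n_male < 4:
            raise ValueError("invalid design field n_female/n_male: need >= 4 samples")
        if self.n_batches < 1:
            raise ValueError("invalid design field n_batches: need >= 1")
        if self.replicate_count_per_sample < 1:
            raise ValueError("invalid design field replicate_count_per_sample")
        if self.nb_dispersion <= 0:
            raise ValueError("invalid design field nb_dispersion: must be > 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or lo > hi:
            raise ValueError("invalid design field lib_size_range")
        names: list[str] = []
        for p in self.gametolog_pairs:
            if p.planted_outcome not in GAMETOLOG_OUTCOMES:
                raise ValueError(
                    f"invalid design field gametolog_pairs: outcome {p.planted_outcome!r}"
                )
            names += [p.x_name, p.y_name]
        if len(names) != len(set(names)):
            raise ValueError("invalid design field gametolog_pairs: duplicate names")


def _sample_ids(design: SimulationDesign) -> tuple[list[str], list[str]]:
    """Biological sample ids, female first; deterministic naming shared by
    simulate_experiment and simulate_qc_profiles."""
    females = [f"F{i + 1:03d}" for i in range(design.n_female)]
    males = [f"M{i + 1:03d}" for i in range(design.n_male)]
    return females, males


def _gene_table(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene class, baseline log2 CPM and planted female/male effect."""
    rows = []

    def add(name, cls, base, lfc_f, is_sexde, partner=None):
        rows.append((name, cls, base, lfc_f, is_sexde, partner))

    # markers first so they always exist
    add(XIST, "X", np.log2(XIST_CPM_MALE), np.log2(XIST_CPM_FEMALE / XIST_CPM_MALE), True)
    for ym in Y_MARKERS:
        add(ym, "Y", np.log2(Y_MARKER_CPM_MALE), -np.inf, True)
    for i in range(design.n_genes_y_linked):
        add(f"YGENE{i + 1:04d}", "Y", np.log2(Y_MARKER_CPM_MALE), -np.inf, True)
    for i in range(design.n_genes_x_escape):
        base = rng.uniform(2.0, 7.0)
        lfc = rng.uniform(0.5, 1.5)  # escape from X inactivation: < ~3-fold
        add(f"XESC{i + 1:04d}", "X", base, lfc, True)
    for i in range(design.n_genes_autosomal_sexde):
        # planted effects are meant to be measurable: keep them clear of
        # the expression filter
        base = rng.uniform(5.0, 8.0)
        sign = 1.0 if i % 2 == 0 else -1.0  # balanced directions
        add(f"ASD{i + 1:05d}", "autosome", base, sign * design.effect_size_log2fc, True)
    for i in range(design.n_genes_autosomal_null):
        base = rng.uniform(0.0, 9.0)
        add(f"ANULL{i + 1:05d}", "autosome", base, 0.0, False)
    for p in design.gametolog_pairs:
        male_x = 2.0**p.x_base_log2cpm
        male_y = p.y_fraction_of_x * male_x
        male_sum = male_x + male_y
        if p.planted_outcome == "unchanged":
            female_x = 2.0 * male_sum
        elif p.planted_outcome == "lost":
            female_x = male_sum
        elif p.planted_outcome == "flipped":
            female_x = 2.0 * male_x
        else:  # gained
            female_x = male_x
        add(p.x_name, "X", p.x_base_log2cpm, np.log2(female_x / male_x), True, p.y_name)
        add(
            p.y_name,
            "Y",
            np.log2(male_y) if male_y > 0 else -np.inf,
            -np.inf,
            True,
            p.x_name,
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "gene_class",
            "base_log2cpm_male",
            "true_log2fc_f_vs_m",
            "is_sexde",
            "gametolog_partner",
        ],
    ).set_index("gene")
    if df.index.has_duplicates:
        raise ValueError(
            "invalid design field gametolog_pairs: names collide with generated genes"
        )
    return df


def simulate_experiment(design: SimulationDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a CountMatrix and its truth table.

    Counts are negative binomial with mean = target CPM x libsize / 1e6
    and fixed dispersion; batch offsets are drawn per (gene, batch) on the
    log2 scale before sampling; technical replicates share one biological
    expression profile (and replicate_group id) but get independent
    library sizes and NB draws. The autosomal null genes act as the
    background transcriptome: their overall level is scaled per sample so
    the expected CPM composition sums to one million, which keeps marker
    and planted genes on their stated CPM scale. Identical seed,
    identical output.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = _gene_table(design, rng)
    females, males = _sample_ids(design)
    bio = females + males
    sexes = ["female"] * len(females) + ["male"] * len(males)
    batches = [f"batch{(i % design.n_batches) + 1}" for i in range(len(bio))]

    g = len(genes)
    base = genes["base_log2cpm_male"].to_numpy(dtype=float)
    lfc = genes["true_log2fc_f_vs_m"].to_numpy(dtype=float)

    # per-(gene, batch) log2 offsets
    batch_levels = sorted(set(batches))
    batch_off = {
        b: rng.normal(0.0, design.batch_effect_sd, size=g) for b in batch_levels
    }
    # a gametolog pair shares its batch offsets: the planted X-vs-(X+Y)
    # outcome is a contract on the pair's relative means, which an
    # independent technical offset on the Y member would break
    idx = {name: i for i, name in enumerate(genes.index)}
    for p in design.gametolog_pairs:
        for b in batch_levels:
            batch_off[b][idx[p.y_name]] = batch_off[b][idx[p.x_name]]

    lo, hi = design.lib_size_range
    disp = design.nb_dispersion
    # background (autosomal null) genes absorb the remaining CPM budget so
    # marker and planted genes keep their stated CPM scale; when there is
    # no background the whole composition is closed to 1e6 instead
    is_bg = np.asarray(genes.index.str.startswith("ANULL"))
    cols, col_ids, meta_rows = [], [], []
    for s, sex, batch in zip(bio, sexes, batches):
        log2cpm = base.copy()
        if sex == "female":
            log2cpm = log2cpm + lfc  # -inf effect -> zero expression
        finite = np.isfinite(log2cpm)
        mu_cpm = np.where(finite, 2.0 ** np.where(finite, log2cpm, 0.0), 0.0)
        mu_cpm = mu_cpm * 2.0 ** batch_off[batch]
        planted_mass = mu_cpm[~is_bg].sum()
        bg_mass = mu_cpm[is_bg].sum()
        if bg_mass > 0 and planted_mass < 1e6:
            mu_cpm[is_bg] *= (1e6 - planted_mass) / bg_mass
        else:
            mu_cpm = mu_cpm / mu_cpm.sum() * 1e6
        for r in range(design.replicate_count_per_sample):
            lib = rng.integers(lo, hi + 1)
            mu = mu_cpm * lib / 1e6
            # NB with var = mu + disp * mu^2 (gamma-Poisson mixture); the
            # multiplicative gamma term is the biological sample effect
            gmult = rng.gamma(1.0 / disp, disp, size=g)
            # the two copies of a gametolog pair co-vary within a sample:
            # sharing the multiplier makes the male X+Y sum NB(mu_x+mu_y,
            # disp), distribution-matched to a single gene at that mean
            for p in design.gametolog_pairs:
                gmult[idx[p.y_name]] = gmult[idx[p.x_name]]
            counts = rng.poisson(mu * gmult)
            sid = s if design.replicate_count_per_sample == 1 else f"{s}_rep{r + 1}"
            cols.append(counts)
            col_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "target_lib_size": int(lib),
                    "sex": sex,
                    "batch": batch,
                    "lane": f"L{r + 1}",
                    "birth_weight_kg": round(
                        rng.normal(3.3 if sex == "female" else 3.6, 0.4), 3
                    ),
                    "ancestry_pc1": round(rng.normal(0.0, 1.0), 4),
                    "ancestry_pc2": round(rng.normal(0.0, 1.0), 4),
                    "replicate_group": s,
                }
            )

    counts = pd.DataFrame(
        np.column_stack(cols), index=genes.index, columns=col_ids
    ).astype(np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    # replicate-level covariates must agree within a placenta
    for col in ("birth_weight_kg", "ancestry_pc1", "ancestry_pc2"):
        meta[col] = meta.groupby("replicate_group")[col].transform("first")

    ann = pd.DataFrame(
        {
            "chrom_class": genes["gene_class"],
            "length_bp": np.round(
                2.0 ** rng.uniform(np.log2(500), np.log2(10_000), size=g)
            ).astype(int),
            "gametolog_partner": genes["gametolog_partner"],
        },
        index=genes.index,
    )
    cm = CountMatrix(counts, ann, meta)
    truth = pd.DataFrame(
        {
            "gene": genes.index,
            "true_log2fc_f_vs_m": genes["true_log2fc_f_vs_m"].to_numpy(),
            "gene_class": genes["gene_class"].to_numpy(),
            "is_sexde": genes["is_sexde"].to_numpy(),
            "gametolog_partner": genes["gametolog_partner"].to_numpy(),
        }
    ).set_index("gene")
    return cm, truth


QC_FAIL_MODES = ("low_reads", "high_reads", "gc_fail", "sex_mismatch", "pass")


def simulate_qc_profiles(
    design: SimulationDesign,
    fail_spec: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Per-sample QC records (reads post trim, GC deviation, reported sex)
    with planted failures.

    Passing samples draw read counts around 35M inside the 12.5M-90M
    window and GC deviation fractions well under 0.30; each failing
    sample violates exactly the named rule.
    """
    design.validate()
    females, males = _sample_ids(design)
    bio = females + males
    modes = dict.fromkeys(bio, "pass")
    for sample, mode in fail_spec:
        if sample not in modes:
            raise ValueError(f"unknown sample {sample!r} in fail_spec")
        if mode not in QC_FAIL_MODES:
            raise ValueError(f"unknown fail mode {mode!r} for sample {sample!r}")
        modes[sample] = mode
    rng = np.random.default_rng(np.random.default_rng(design.seed).integers(2**31))
    rows = []
    for s in bio:
        sex = "female" if s in set(females) else "male"
        reads = int(rng.normal(35_000_000, 5_000_000))
        reads = int(np.clip(reads, 15_000_000, 85_000_000))
        gc = float(rng.uniform(0.05, 0.15))
        reported = sex
        mode = modes[s]
        if mode == "low_reads":
            reads = int(rng.uniform(5_000_000, 12_400_000))
        elif mode == "high_reads":
            reads = int(rng.uniform(91_000_000, 120_000_000))
        elif mode == "gc_fail":
            gc = float(rng.uniform(0.31, 0.60))
        elif mode == "sex_mismatch":
            reported = "male" if sex == "female" else "female"
        rows.append(
            {
                "sample": s,
                "reads_post_trim": reads,
                "gc_deviation_fraction": gc,
                "reported_sex": reported,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def simulate_tissue_panel(
    base_truth: pd.DataFrame,
    n_tissues: int = 5,
    shared_sexlinked: bool = True,
    autosomal_tissue_sd: float = 0.5,
    seed: int = 0,
    measurement_sd: float = 0.05,
) -> pd.DataFrame:
    """Per-tissue, per-gene mean TPM by sex.

    Sex-linked genes (classes X, Y, X_PAR) carry the base truth's F/M
    effect in every tissue when ``shared_sexlinked``; autosomal sex
    effects are re-drawn per tissue as N(0, autosomal_tissue_sd),
    i.e. tissue-specific and uncorrelated with the base. A small log2
    measurement noise (``measurement_sd``) is added to each sex mean.

    Returns a long table (tissue, gene, mean_tpm_female, mean_tpm_male).
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    if autosomal_tissue_sd < 0 or measurement_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    genes = base_truth.index.to_numpy()
    cls = base_truth["gene_class"].to_numpy()
    lfc = base_truth["true_log2fc_f_vs_m"].to_numpy(dtype=float)
    sexlinked = np.isin(cls, ("X", "Y", "X_PAR"))
    # base male TPM level, shared across tissues
    base_tpm = 2.0 ** rng.uniform(0.0, 8.0, size=len(genes))
    rows = []
    for t in range(n_tissues):
        tissue = f"tissue{t + 1:02d}"
        eff = np.where(sexlinked & shared_sexlinked, lfc, 0.0)
        if autosomal_tissue_sd > 0:
            eff = eff + np.where(
                sexlinked, 0.0, rng.normal(0.0, autosomal_tissue_sd, size=len(genes))
            )
        male = base_tpm.copy()
        with np.errstate(over="ignore"):
            female = np.where(np.isfinite(eff), base_tpm * 2.0**eff, 0.0)
        if measurement_sd > 0:
            male = male * 2.0 ** rng.normal(0.0, measurement_sd, size=len(genes))
            female = female * 2.0 ** rng.normal(0.0, measurement_sd, size=len(genes))
        rows.append(
            pd.DataFrame(
                {
                    "tissue": tissue,
                    "gene": genes,
                    "mean_tpm_female": female,
                    "mean_tpm_male": male,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
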