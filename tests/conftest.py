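import numpy as np
import pandas as pd
import pytest

import sexdiff as sd


def make_count_matrix(counts, chrom_class=None, lengths=None, meta=None):
    """Minimal CountMatrix from a plain dict/array of counts."""
    counts = pd.DataFrame(counts)
    g = counts.shape[0]
    ann = pd.DataFrame(
        {
            "chrom_class": chrom_class if chrom_class is not None else ["autosome"] * g,
            "length_bp": lengths if lengths is not None else [1000] * g,
            "gametolog_partner": [None] * g,
        },
        index=counts.index,
    )
    if meta is None:
        n = counts.shape[1]
        meta = pd.DataFrame(
            {
                "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
                "batch": ["b1"] * n,
                "lane": ["L1"] * n,
                "replicate_group": list(counts.columns),
            },
            index=counts.columns,
        )
    return sd.CountMatrix(counts, ann, meta)


@pytest.fixture(scope="session")
def small_experiment():
    """20 vs 20 synthetic experiment with planted autosomal effects,
    escapers, Y genes and all four gametolog scenarios."""
    design = sd.SimulationDesign(
        n_female=20,
        n_male=20,
        n_genes_autosomal_null=400,
        n_genes_autosomal_sexde=40,
        n_genes_x_escape=10,
        n_genes_y_linked=8,
        gametolog_pairs=(
            sd.GametologSpec("GX1", "GY1", 4.0, 0.0, "unchanged"),
            sd.GametologSpec("GX2", "GY2", 4.0, 1.0, "lost"),
            sd.GametologSpec("GX3", "GY3", 4.0, 4.0, "flipped"),
            sd.GametologSpec("GX4", "GY4", 4.0, 1.0, "gained"),
        ),
        replicate_count_per_sample=1,
        seed=101,
    )
    cm, truth = sd.simulate_experiment(design)
    return design, cm, truth


@pytest.fixture(scope="session")
def small_fit(small_experiment):
    _, cm, _ = small_experiment
    return sd.SexDEModel(cm, covariates=["batch"]).fit()
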