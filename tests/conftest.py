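"""Shared fixtures.

The global-null calibration run (20 pathways x 50 tag-loci, 60 disease + 15
control samples, 200-tree forests, 100 pooled permutations) is expensive, so
it is computed once per session and shared between the acceptance criterion
and the null-uniformity property tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pwcnaqtl.association import ForestParams
from pwcnaqtl.io_model import CONTROL, DISEASE, ExpressionMatrix
from pwcnaqtl.pipeline import RunConfig, run_pipeline
from pwcnaqtl.synthetic_data import SyntheticConfig

NULL_CALIBRATION_SEED = 20230


def make_expression(
    values: np.ndarray,
    n_disease: int,
    genes: list[str] | None = None,
    prefix: str = "G",
) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix; first n_disease columns are
    disease samples, the rest controls."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"{prefix}{i + 1}" for i in range(n_genes)]
    samples = [f"D{i + 1}" for i in range(n_disease)] + [
        f"C{i + 1}" for i in range(n_samples - n_disease)
    ]
    labels = {
        s: DISEASE if i < n_disease else CONTROL for i, s in enumerate(samples)
    }
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), labels
    )


@pytest.fixture(scope="session")
def null_calibration():
    """Full pipeline on a global-null synthetic dataset (no planted effects).

    20 pathways, 50 tag-loci (5 chromosomes x 20 loci in blocks of 2),
    60 disease + 15 control samples, 200-tree forests, 100 permutations,
    pooled null, fixed seed.
    """
    config = RunConfig(
        seed=NULL_CALIBRATION_SEED,
        outdir="scratch/null_calibration",
        synthetic=SyntheticConfig(
            n_disease=60,
            n_control=15,
            n_chromosomes=5,
            loci_per_chromosome=20,
            block_size=2,
            within_block_r=0.99,
            n_pathways=20,
            genes_per_pathway=8,
            n_background_genes=60,
            seed=NULL_CALIBRATION_SEED,
        ),
        forest=ForestParams(n_trees=200, min_node_size=2),
        n_perm=100,
        null_pooling="pooled",
        alpha=0.05,
    )
    return run_pipeline(config)
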