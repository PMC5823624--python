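import numpy as np
import pandas as pd
import pytest

from paradoxcna.formats_io import ExpressionMatrix
from paradoxcna.synthetic_cohort import SimulationConfig


@pytest.fixture
def small_config():
    """A fast, fully-featured synthetic study for smoke-level tests."""
    return SimulationConfig(
        n_genes=300, n_mirnas=20, n_cna_datasets=2, n_expr_datasets=4,
        samples_per_dataset=30, normals_per_dataset=10, n_chromosomes=3,
        aberrant_region_count=4, n_paradox_genes=12,
        n_deregulated_mirnas=6, n_mirna_studies=6,
        probes_per_chromosome=30, matched_tumors=60, matched_normals=20,
        seed=11)


def make_matrix(tumor: np.ndarray, normal: np.ndarray,
                feature_ids=None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from tumor and normal blocks."""
    n_feat = tumor.shape[0]
    feature_ids = feature_ids or [f"g{i}" for i in range(n_feat)]
    tum = [f"t{j}" for j in range(tumor.shape[1])]
    nor = [f"n{j}" for j in range(normal.shape[1])]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=feature_ids,
                          columns=tum + nor)
    classes = {**{s: "tumor" for s in tum}, **{s: "normal" for s in nor}}
    return ExpressionMatrix(values=values, sample_class=classes)
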