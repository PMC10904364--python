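import warnings

import numpy as np
import pandas as pd
import pytest

from plexcell.synthetic import (
    TissuePhantomSpec,
    simulate_expression_table,
    simulate_tissue_image,
)

# scanpy / umap emit benign deprecation chatter
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="umap")


@pytest.fixture(scope="session")
def default_spec() -> TissuePhantomSpec:
    return TissuePhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom_table(default_spec):
    """Default expression-table phantom: (table, ground_truth)."""
    return simulate_expression_table(default_spec)


@pytest.fixture(scope="session")
def phantom_image():
    """Small noise-free image phantom: (spec, stack, labels, ground_truth)."""
    spec = TissuePhantomSpec(
        seed=3, noise_sd=0.0, n_cells=60, n_erythrocytes=8,
        image_shape=(384, 384), n_cores=1,
    )
    stack, labels, gt = simulate_tissue_image(spec)
    return spec, stack, labels, gt


@pytest.fixture(scope="session")
def clean_labeled_table(phantom_table, default_spec):
    """Phantom table after QC cleaning, joined with ground truth."""
    from plexcell.qc import ArtifactClusteringConfig, run_cleaning

    table, gt = phantom_table
    clean, report = run_cleaning(table, ArtifactClusteringConfig(seed=0))
    merged = clean.merge(
        gt[["cell_id", "true_phenotype", "is_artifact"]], on="cell_id"
    )
    return merged, report
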