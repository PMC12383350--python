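import numpy as np
import pytest

from otperturb.data_io import (
    CONTROL,
    NORMALIZED_LOG,
    RAW_COUNTS,
    STIMULATED,
    ExpressionDataset,
    RunConfig,
)
from otperturb.simulate import SimConfig, simulate_dataset


def make_dataset(
    matrix,
    cell_type=None,
    condition=None,
    layer_tag=RAW_COUNTS,
    gene_ids=None,
):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    return ExpressionDataset(
        matrix=matrix,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array(
            gene_ids if gene_ids is not None else [f"g{j}" for j in range(d)],
            dtype=object,
        ),
        cell_type=np.array(
            cell_type if cell_type is not None else ["A"] * n, dtype=object
        ),
        condition=np.array(
            condition if condition is not None else [CONTROL] * n, dtype=object
        ),
        layer_tag=layer_tag,
    )


@pytest.fixture
def tiny_dataset():
    """10 cells x 4 genes, two types, both conditions."""
    rng = np.random.default_rng(42)
    matrix = rng.poisson(5.0, size=(10, 4)).astype(float) + 1.0
    return make_dataset(
        matrix,
        cell_type=["A"] * 5 + ["B"] * 5,
        condition=([CONTROL] * 3 + [STIMULATED] * 2) * 2,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulated dataset with ground truth (session-cached)."""
    cfg = SimConfig(
        n_cell_types=3,
        cells_per_type_per_condition=80,
        n_genes=200,
        n_response_genes=30,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_processed(small_sim):
    from otperturb.cli import preprocess_dataset

    dataset, truth = small_sim
    cfg = RunConfig(
        min_genes_per_cell=30, min_cells_per_gene=3, hvg_count=200, seed=7
    )
    return preprocess_dataset(dataset, cfg), truth


@pytest.fixture(scope="session")
def small_model(small_processed):
    """A quickly trained model on the small fixture (session-cached)."""
    from otperturb.mmdvae import train
    from otperturb.preprocess import holdout_split

    processed, truth = small_processed
    cfg = RunConfig(
        seed=7,
        latent_dim=12,
        hidden_widths=[48, 48],
        epochs=40,
        batch_size=32,
        dropout=0.0,
        alpha=1.0,
        top_k=10,
        min_genes_per_cell=30,
        min_cells_per_gene=3,
        hvg_count=200,
    )
    train_set, test_control, test_stimulated = holdout_split(processed, "type0")
    model = train(train_set, None, cfg)
    return model, cfg, train_set, test_control, test_stimulated
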