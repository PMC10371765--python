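import numpy as np
import pytest

from precancell import (
    MALIGNANT,
    NON_MALIGNANT,
    ExpressionMatrix,
    Normalization,
    ReferenceDataset,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230711)


def make_matrix(values, normalization=Normalization.RAW, gene_prefix="g", cell_prefix="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{cell_prefix}{j}" for j in range(values.shape[1])],
        normalization,
    )


def make_separated_reference(
    seed, n_per_class=30, n_markers=20, n_noise=10, separation=2.0, noise_sd=1.0, name="ref"
):
    """Two Gaussian-mean classes separated on marker features, plus noise genes.

    Malignant cells center at +separation/2, non-malignant at -separation/2
    on each marker gene (values shifted to stay non-negative), with
    within-class SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    n_cells = 2 * n_per_class
    labels = np.array([MALIGNANT] * n_per_class + [NON_MALIGNANT] * n_per_class)
    centers = np.where(labels == MALIGNANT, separation / 2, -separation / 2)
    marker_vals = centers + rng.normal(0, noise_sd, size=(n_markers, n_cells))
    noise_vals = rng.normal(0, noise_sd, size=(n_noise, n_cells))
    values = np.vstack([marker_vals, noise_vals])
    values = values - values.min()  # log-normalized matrices are non-negative
    genes = [f"mk{i}" for i in range(n_markers)] + [f"nz{i}" for i in range(n_noise)]
    expr = ExpressionMatrix(
        values,
        genes,
        [f"{name}_c{j}" for j in range(n_cells)],
        Normalization.UMI_LOGNORM,
    )
    return ReferenceDataset(expr=expr, labels=labels, name=name)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation for fast unit tests."""
    return SimulationConfig(
        n_malignant=80,
        n_non_malignant=80,
        n_genes=400,
        n_tmg_planted=10,
        n_nmg_planted=15,
        effect_size=2.0,
        dropout_rate=0.2,
        dispersion=0.5,
        library_size_mean=2000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config)
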