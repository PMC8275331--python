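import numpy as np
import pytest

from moable.coembedding import TrainConfig
from moable.synthetic_data import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


TINY_SIM = dict(
    n_compounds=40, n_genes=10, n_pathways=2, genes_per_pathway=5,
    n_bits=256, sig_dim=64, replicates_per_gene=2, signatures_per_compound=2,
    motif_bits_per_target=16, decoy_compound_fraction=0.0,
)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small linked corpus for fast unit tests (40 compounds over 10 genes)."""
    return simulate(SimConfig(**TINY_SIM, seed=123))


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(margin_alpha=1.0, learning_rate=3e-4, batch_size=64,
                       max_epochs=40, patience=10, seed=5)
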