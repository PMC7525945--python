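import pytest

from essgene.corpus import GeneRecord
from essgene.datasets import balance_by_downsampling
from essgene.features import feature_table
from essgene.mlp import ModelConfig
from essgene.simulate import SyntheticConfig, generate_corpus


@pytest.fixture()
def tiny_records():
    """Three hand-written gene records with valid DNA/protein pairing."""
    return [
        GeneRecord("g1", "SP1", "ATGAAAAAATGA", "MKK", True, "c1"),
        GeneRecord("g2", "SP1", "ATGGGCGGATGA", "MGG", False, "c1"),
        GeneRecord("g3", "SP2", "ATGTTTAAATAA", "MFK", False, "c2"),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus shared by split/training tests."""
    config = SyntheticConfig(n_species=3, genes_per_species=250, seed=11)
    records, cmap = generate_corpus(config)
    return records, cmap


@pytest.fixture(scope="session")
def small_frame(small_corpus):
    records, _ = small_corpus
    return feature_table(records)


@pytest.fixture(scope="session")
def balanced_small(small_corpus):
    records, _ = small_corpus
    return balance_by_downsampling(records, seed=7)


@pytest.fixture()
def fast_model_config():
    """A reduced architecture for tests where training time matters."""
    return ModelConfig(
        hidden_dims=(64, 32),
        max_epochs=30,
        early_stopping_patience=5,
        batch_size=128,
        seed=0,
    )
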