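import numpy as np
import pytest

from psychembed.corpus import EmbeddingTable, IdfTable
from psychembed.simdata import SimConfig, simulate_study


@pytest.fixture
def tiny_space():
    """Hand-built 2-D embedding + IDF tables for exact arithmetic checks."""
    emb = EmbeddingTable(
        dimension=2,
        entries={
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
        },
    )
    idf = IdfTable(n_documents=10, weights={"a": 1.0, "b": 2.0, "c": 0.5})
    return emb, idf


@pytest.fixture(scope="session")
def small_study():
    """Desk-size synthetic study with strong group separation."""
    cfg = SimConfig(n_patients=120, embed_dim=20, vocab_size=100, seed=1)
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def signal_study():
    """Synthetic study at the strong-effect evaluation settings."""
    cfg = SimConfig(
        n_patients=300, embed_dim=50, vocab_size=500, effect_size=2.0, seed=0
    )
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Synthetic study with no group effect (null calibration)."""
    cfg = SimConfig(
        n_patients=300, embed_dim=50, vocab_size=500, effect_size=0.0, seed=0
    )
    return cfg, simulate_study(cfg)
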