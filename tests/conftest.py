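import numpy as np
import pytest

from pathddi.config import RunConfig
from pathddi.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_cfg():
    """Desk-scale configuration for fast model tests."""
    return RunConfig(L=32, d_emb=16, d_model=16, n_layers=1, n_head=2,
                     d_ff=32, K_heads=2, d_prime=8, d_kg=20,
                     conv_channels=8, embedding_dim=16, max_epochs=3,
                     n_folds=2, walk_steps=50, walk_iterations=20,
                     walk_spread=60, seed=0)


@pytest.fixture
def tiny_spec():
    return SyntheticSpec(n_drugs=12, n_pathways=5, n_diseases=3,
                         n_side_effects=3, mediator_density=0.3,
                         n_classes=3, n_pairs=40, embedding_dim=16, seed=0)
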