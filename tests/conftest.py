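import numpy as np
import pytest

from protlabel.network import Hyperparams
from protlabel.synthetic import FixtureConfig, generate_multitask_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture_tasks():
    """Two noise-free correlated tasks, shared latent path, with profiles."""
    cfg = FixtureConfig(
        n_proteins=12, length_range=(30, 40), n_tasks=2, n_states=3,
        noise=0.0, share_proteins=False, n_folds=3, seed=7,
    )
    return generate_multitask_fixture(cfg)


@pytest.fixture
def fast_hyper():
    """Hyperparameters sized for sub-second training in unit tests."""
    return Hyperparams(
        window=5, embed_dim=4, hidden_units=12, lr=0.05,
        max_iters=4, updates_per_iter=800, seed=3,
    )
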