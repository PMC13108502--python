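import numpy as np
import pytest

from dynconn import (
    ModularityConfig,
    PlantedMultilayerSpec,
    generate_planted_stack,
    run_ensemble,
)


@pytest.fixture(scope="session")
def planted_stack():
    """Noise-free 2-community stack with one switcher (exact ground truth)."""
    spec = PlantedMultilayerSpec(
        n_nodes=12, n_layers=4, n_communities=2,
        switchers=frozenset({3}), switch_layers=frozenset({2}),
    )
    return generate_planted_stack(spec)


@pytest.fixture(scope="session")
def small_ensemble(planted_stack):
    stack, _ = planted_stack
    return run_ensemble(stack, ModularityConfig(n_iter=10, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
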