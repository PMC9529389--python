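import numpy as np
import pytest

from noduleboost.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Quick 5+5-candidate phantom for unit tests."""
    cfg = PhantomConfig(
        volume_shape=(64, 200, 200), n_nodules=5, n_nonnodules=5,
        vessel_count=10, seed=1,
    )
    volume, candidates = generate_phantom(cfg)
    return cfg, volume, candidates


@pytest.fixture(scope="session")
def bench_phantom():
    """The standard 50+50 bench phantom (the spec'd pairwise-check instance)."""
    cfg = PhantomConfig(seed=7)
    volume, candidates = generate_phantom(cfg)
    return cfg, volume, candidates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
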