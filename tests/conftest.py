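import numpy as np
import pytest

from uitrans import synthetic as syn
from uitrans.model import UITransConfig


@pytest.fixture(scope="session")
def phantom32():
    return syn.generate_heart_phantom((32, 32, 32), seed=3)


@pytest.fixture(scope="session")
def pair32(phantom32):
    return syn.make_training_pair(phantom32, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest dual-branch config that exercises every code path."""
    return UITransConfig(n_stages=2, base_channels=4, n_heads=2,
                        embed_dim=8, token_stride=2)


# -- heavy, shared end-to-end pipelines (computed once per session) -----------


@pytest.fixture(scope="session")
def restoration_run():
    from uitrans.benchmarks import restoration_benchmark
    return restoration_benchmark(seed=11)


@pytest.fixture(scope="session")
def overfit_run():
    from uitrans.benchmarks import overfit_benchmark
    return overfit_benchmark(seed=3, steps=400)
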