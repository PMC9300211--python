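import numpy as np
import pytest

from hairpinxb.synthetic import (GeneratorConfig, generate_pool,
                                 pool_truth_populations)


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def small_pool(default_cfg):
    """Default 10 folded + 10 unfolded pool with truth labels."""
    return generate_pool(default_cfg)


@pytest.fixture(scope="session")
def uniform_populations(small_pool):
    _, truth = small_pool
    return pool_truth_populations(truth, folded_share=0.5).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
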