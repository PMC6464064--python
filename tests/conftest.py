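import numpy as np
import pytest

from regcl import SimConfig, iPWM, run_planted_benchmark
from regcl.synthetic import gen_ipwm

# toy 2-position matrix: position 1 favors A, position 2 favors C;
# consensus "AC" scores 4.0 bits
TOY2_WEIGHTS = np.array(
    [
        [2.0, -1.0, -1.0, -1.0],
        [-1.0, 2.0, -1.0, -1.0],
    ]
)


@pytest.fixture
def toy2() -> iPWM:
    return iPWM(tf="TOY2", weights=TOY2_WEIGHTS.copy(), r_sequence_meta=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sim_ipwm() -> iPWM:
    return iPWM.from_file(gen_ipwm(12, 15.0, seed=7))


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced planted-target run shared by tests that only need its pieces."""
    return run_planted_benchmark(
        5, cfg=SimConfig(n_genes=60, n_positives=30), rounds=2, folds=5
    )
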