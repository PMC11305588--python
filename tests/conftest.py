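import numpy as np
import pytest

from ismpop import run_preset


@pytest.fixture(scope="session")
def set2_A_runs():
    return run_preset("set2_A_sweep", seed=11)


@pytest.fixture(scope="session")
def set2_C_runs():
    return run_preset("set2_C_sweep", seed=11)


@pytest.fixture(scope="session")
def ladder_run():
    (traj,) = run_preset("set1_innovation_ladder", seed=11)
    return traj


@pytest.fixture
def rng():
    return np.random.default_rng(20240807)
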