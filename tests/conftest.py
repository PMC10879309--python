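import numpy as np
import pytest

from synergidca import (SceneConfig, TraceSimConfig, make_preset,
                        simulate_synergid_pair)


@pytest.fixture(scope="session")
def short_sim_cfg():
    """A 5-minute acquisition, long enough for several wild-type transients."""
    return TraceSimConfig(seed=3, duration_min_s=300.0, duration_max_s=300.0)


@pytest.fixture(scope="session")
def wt_pair(short_sim_cfg):
    (left, truth_l), (right, truth_r) = simulate_synergid_pair(
        make_preset("wildtype"), short_sim_cfg)
    return left, right, truth_l, truth_r


@pytest.fixture(scope="session")
def noiseless_scene():
    return SceneConfig().noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
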