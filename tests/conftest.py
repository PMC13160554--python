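import numpy as np
import pytest

import olfdrift as od
from olfdrift.network import scaled_rules


@pytest.fixture(scope="session")
def mini_rules():
    return scaled_rules(od.MINI_SPEC)


@pytest.fixture(scope="session")
def mini_net(mini_rules):
    return od.build_network(od.MINI_SPEC, mini_rules, rng=12345)


@pytest.fixture(scope="session")
def mini_params():
    return od.draw_all_params(od.MINI_SPEC, np.random.default_rng(777))


@pytest.fixture(scope="session")
def mini_panel():
    return od.generate_panel(10, od.MINI_SPEC.n_glomeruli, rng=99)


@pytest.fixture(scope="session")
def mini_sim(mini_net, mini_params):
    return od.Simulator(mini_net, mini_params, od.SimConfig())


@pytest.fixture(scope="session")
def mini_raster(mini_sim, mini_panel):
    return mini_sim.run_trial(mini_panel[0], 2024)
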