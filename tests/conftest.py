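import numpy as np
import pytest

from choicebias.beast import BeastConfig
from choicebias.data import Lottery, Problem
from choicebias.synth import SynthConfig, make_paired_datasets


@pytest.fixture(scope="session")
def worked_lotteries():
    """The three-outcome lottery pair where A first-order dominates B."""
    a = Lottery([12, 14, 96], [0.05, 0.05, 0.90])
    b = Lottery([12, 90, 96], [0.10, 0.05, 0.85])
    return a, b


@pytest.fixture
def simple_problem():
    return Problem(id="p1", ha=90.0, p_ha=0.05, la=12.0,
                   hb=50.0, p_hb=0.5, lb=0.0)


@pytest.fixture(scope="session")
def paired_data():
    """Small aligned lab/online synthetic datasets shared across tests."""
    cfg = SynthConfig(n_problems=300, seed=7, n_blocks=1, n_participants=15,
                      noise_f=0.6, noise_p_guess=0.25)
    return make_paired_datasets(cfg, BeastConfig(n_agents=1000, seed=8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
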