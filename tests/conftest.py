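import numpy as np
import pytest

from glycontrol import preset_model, solve_steady_state


@pytest.fixture(scope="session")
def as30d():
    return preset_model("AS30D")


@pytest.fixture(scope="session")
def hela_hypo():
    return preset_model("HeLa_hypo")


@pytest.fixture(scope="session")
def as30d_ss(as30d):
    ss = solve_steady_state(as30d)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def hela_hypo_ss(hela_hypo):
    ss = solve_steady_state(hela_hypo)
    assert ss.converged
    return ss


def random_state(rng, species, lo=0.01, hi=10.0):
    """Random physiological-range concentration state over given species."""
    return {s: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for s in species}


@pytest.fixture
def rng():
    return np.random.default_rng(20160923)
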