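import numpy as np
import pytest

from mhspc_cea.cost_model import load_parameters
from mhspc_cea.econ_eval import CEModel
from mhspc_cea.markov_engine import ModelSettings


@pytest.fixture(scope="session")
def params():
    return load_parameters()


def _exp_sf(rate):
    return lambda t: np.exp(-rate * np.asarray(t, dtype=float))


@pytest.fixture(scope="session")
def exp_model(params):
    """A small CEModel on exponential curves (per-month rates chosen so
    the treated arm progresses later and dies later)."""
    curves = {
        "rezvilutamide": (_exp_sf(0.02), _exp_sf(0.012)),
        "bicalutamide": (_exp_sf(0.0276), _exp_sf(0.018)),
    }
    return CEModel(curves, params, ModelSettings(discount_annual=0.05))
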