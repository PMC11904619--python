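import numpy as np
import pytest

import ikrfit as ik

E_NERNST = -89.85  # mV, potassium Nernst potential of the study solutions


@pytest.fixture(scope="session")
def staircase_1ms():
    return ik.staircase_like(sample_interval=1.0)


@pytest.fixture(scope="session")
def staircase_10ms():
    return ik.staircase_like(sample_interval=10.0)


@pytest.fixture(scope="session")
def all_models():
    return {name: ik.build_model(name) for name in ("COI", "Beattie", "Kemp", "Wang")}


@pytest.fixture(scope="session")
def beattie_sim_10ms(staircase_10ms):
    """Noiseless Beattie staircase simulation reused across tests."""
    model = ik.build_model("Beattie")
    params = ik.default_parameters(model)
    sim = ik.simulate_current(model, params, staircase_10ms, E_Kr=E_NERNST)
    return model, params, sim
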