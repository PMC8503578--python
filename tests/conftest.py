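import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from ictalcoh.sensors import SensorArray, make_shaft, standard_scalp_cap
from ictalcoh.sphere import HeadModel


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def cap_positions(head):
    cap = standard_scalp_cap(head)
    return np.array([p for _, p in cap])


@pytest.fixture(scope="session")
def sensors(head):
    u = np.array([0.55, -0.35, 0.76])
    u /= np.linalg.norm(u)
    shaft = make_shaft("V", head.center + 24.5 * u, u, n_contacts=16)
    return SensorArray(scalp=standard_scalp_cap(head), shafts=[shaft])


@pytest.fixture(scope="session")
def small_session():
    """One shallow-source session at reduced scale, shared across tests."""
    from ictalcoh.simulate import (SimulationConfig, depth_scenario,
                                   simulate_session)

    cfg, sens, hd, sources = depth_scenario(
        0.8, seed=7, config=SimulationConfig(fs=256.0, duration=36.0, seed=7))
    scalp, seeg, gt = simulate_session(cfg, sens, hd, sources)
    return {"config": cfg, "sensors": sens, "head": hd, "sources": sources,
            "scalp": scalp, "seeg": seeg, "gt": gt}
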