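import pytest
from hypothesis import settings

import circuitevo as ce
from circuitevo.host import CellModel

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def host():
    return ce.HostParams()


@pytest.fixture(scope="session")
def host_model(host):
    return CellModel(host, None)


@pytest.fixture(scope="session")
def host_steady_state(host_model):
    return host_model.steady_state()


@pytest.fixture(scope="session")
def toy_cfg():
    return ce.fixture_toy_system()


@pytest.fixture(scope="session")
def toy_trace(toy_cfg):
    """One shared 3-day open-loop evolution run (fast mutation)."""
    return toy_cfg.run()


@pytest.fixture(scope="session")
def clpatl_trace():
    """Shared 4-day run of a strong sRNA-feedback controller (CLpATL)
    under fast mutation; exhibits controller-promoter mutants."""
    cfg = ce.RunConfig(
        topology="CLpATL",
        design={"omega_A": 50.0, "k_B": 20.0, "omega_C": 100.0},
        mutation={"base_rate": 2e-4},
        protocol={"max_days": 4, "samples_per_day": 12},
    )
    return cfg.run()


@pytest.fixture(scope="session")
def ol_cell(host):
    """Open-loop cell model at the nominal process rate with its
    ancestral steady state."""
    circuit = ce.design("OL", omega_A=5.0)
    model = CellModel(host, circuit)
    return model, model.steady_state()
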