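from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cowgas.accounting import cumulative_balance
from cowgas.simulator import scenario_preset, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _run_preset(name):
    config, params = scenario_preset(name)
    trajectory, series = simulate(config, params)
    balance = cumulative_balance(series)
    return trajectory, series, balance


@pytest.fixture(scope="session")
def dsm2542_run():
    return _run_preset("dsm2542")


@pytest.fixture(scope="session")
def toebii_run():
    return _run_preset("toebii")


@pytest.fixture(scope="session")
def thermo_run():
    return _run_preset("thermodenitrificans")


@pytest.fixture(scope="session")
def abiotic_run():
    return _run_preset("abiotic_control")
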