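import pytest

from thermoflux.synthetic import (
    ToyNetworkSpec,
    make_chain_model,
    make_cycle_model,
    make_temperature_switch_model,
)
from thermoflux.thermo import ThermoConfig
from thermoflux.tmfa import build_problem

T_REF = 288.15
T_LOW = 277.15
T_HIGH = 293.15


@pytest.fixture(scope="session")
def chain():
    """(model, thermo, tables, meta) for the default 3-step chain."""
    return make_chain_model(ToyNetworkSpec(n_linear_steps=3))


@pytest.fixture(scope="session")
def chain_problem(chain):
    model, thermo, tables, _ = chain
    return build_problem(model, thermo, ThermoConfig(temperature_K=T_REF), tables)


@pytest.fixture(scope="session")
def cycle():
    return make_cycle_model()


@pytest.fixture(scope="session")
def cycle_problem(cycle):
    model, thermo, tables, _ = cycle
    return build_problem(model, thermo, ThermoConfig(temperature_K=T_REF), tables)


@pytest.fixture(scope="session")
def switch():
    return make_temperature_switch_model(T_LOW, T_HIGH)


@pytest.fixture(scope="session")
def switch_problems(switch):
    model, thermo, tables, _ = switch
    return {
        T: build_problem(model, thermo, ThermoConfig(temperature_K=T), tables)
        for T in (T_LOW, T_HIGH)
    }
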