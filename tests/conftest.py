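import pytest

import gc_cea as g


@pytest.fixture(scope="session")
def life_table():
    return g.make_life_table()


@pytest.fixture(scope="session")
def settings():
    return g.EconSettings()


@pytest.fixture(scope="session")
def param_list():
    return g.load_parameters()


@pytest.fixture(scope="session")
def base_vals(param_list):
    return g.base_values(param_list)


@pytest.fixture(scope="session")
def traces(settings, life_table):
    """The three cohort traces (transitions are structural constants)."""
    return g.compute_traces(settings, life_table)


@pytest.fixture(scope="session")
def base_outcomes(base_vals, settings, life_table, traces):
    return g.evaluate_strategies(base_vals, settings, life_table, traces)
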