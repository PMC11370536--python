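import pytest

from cohlex import builtin_topologies, solve_rates, solve_steady_state, wild_type_totals


@pytest.fixture(scope="session")
def five_state():
    return builtin_topologies()["five_state"]


@pytest.fixture(scope="session")
def wt_rates(five_state):
    return solve_rates(five_state, "hela_wt")


@pytest.fixture(scope="session")
def wt_totals():
    return wild_type_totals()


@pytest.fixture(scope="session")
def wt_steady(wt_rates, wt_totals):
    return solve_steady_state(wt_rates, wt_totals)
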