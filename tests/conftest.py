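import numpy as np
import pandas as pd
import pytest

import misscausal as mc
from misscausal.simulation import SCENARIO_ROLES, simulate_scenario


@pytest.fixture(scope="session")
def roles():
    return SCENARIO_ROLES


@pytest.fixture(scope="session")
def dgp_i():
    return mc.default_dgp("I")


@pytest.fixture(scope="session")
def dgp_ii():
    return mc.default_dgp("II")


@pytest.fixture(scope="session")
def dgp_iii():
    return mc.default_dgp("III")


@pytest.fixture(scope="session")
def law_ii(dgp_ii):
    return mc.enumerate_law(dgp_ii)


@pytest.fixture(scope="session")
def law_iii(dgp_iii):
    return mc.enumerate_law(dgp_iii)


@pytest.fixture(scope="session")
def sim_table_ii(dgp_ii):
    table, y0, y1 = simulate_scenario(dgp_ii, 2500, seed=424242)
    return table


@pytest.fixture(scope="session")
def sim_table_iii(dgp_iii):
    table, y0, y1 = simulate_scenario(dgp_iii, 2500, seed=424243)
    return table


@pytest.fixture(scope="session")
def sat_specs():
    """Saturated nuisance models without truncation: the exact-agreement regime."""
    return mc.NuisanceSpecs.saturated(truncation=0.0)


@pytest.fixture
def small_table(roles):
    """Six hand-written records with a non-monotone missingness pattern."""
    df = pd.DataFrame(
        {
            "y": [1, 0, 1, 0, 1, 0],
            "a": [1, 0, np.nan, 1, np.nan, 0],
            "l_o": [1, 1, 0, 0, 1, 0],
            "l_m1": [0, 1, np.nan, 1, 0, np.nan],
            "l_m2": [1, np.nan, 0, 1, np.nan, 0],
        }
    )
    return mc.ObservedTable.from_dataframe(df, roles)
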