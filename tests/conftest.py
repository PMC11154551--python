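import numpy as np
import pytest

from ncie import CausalSpec, PanelTable, simulate_boolean, simulate_case

H_Y_BITS = 2 - 0.75 * np.log2(3)          # entropy of the AND target
I_YX_BITS = 1.5 - 0.75 * np.log2(3)       # information from X alone


@pytest.fixture(scope="session")
def boolean_panel():
    return simulate_boolean(5000, seed=7)


@pytest.fixture(scope="session")
def boolean_spec():
    return CausalSpec(target="Y", observed_causes=(("X", 1),), k=0)


@pytest.fixture(scope="session")
def case1_panel():
    return simulate_case(1)


@pytest.fixture(scope="session")
def case2_panel():
    return simulate_case(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_panel(rng):
    n = 200
    x = rng.normal(size=n)
    y = np.empty(n)
    y[0] = 0.0
    for t in range(1, n):
        y[t] = 0.6 * y[t - 1] + 0.5 * x[t - 1] + 0.1 * rng.normal()
    return PanelTable.from_columns({"Y": y, "X": x})
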