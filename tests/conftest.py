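"""Shared fixtures: small simulated panels reused across test modules.

Simulation is the dominant test cost, so panels are session-scoped and the
tests that consume them are read-only.
"""

import numpy as np
import pytest

from recne import scenario, simulate_ld_panel
from recne.genmap import uniform_arm_table


@pytest.fixture(scope="session")
def constant_panel():
    """Diploid panel under the constant N_e = 20,000 scenario (20 arms)."""
    arms = uniform_arm_table(20, 40.0)
    panel, gmap = simulate_ld_panel(scenario("constant"), n_samples=100,
                                    sites_per_arm=70, seed=101, arms=arms)
    return panel, gmap


@pytest.fixture(scope="session")
def collapse_panel():
    """Diploid panel under the exponential-collapse scenario (20 arms)."""
    arms = uniform_arm_table(20, 40.0)
    panel, gmap = simulate_ld_panel(scenario("collapse"), n_samples=100,
                                    sites_per_arm=70, seed=202, arms=arms)
    return panel, gmap


@pytest.fixture()
def rng():
    """Fresh, deterministic generator per test (order-independent data)."""
    return np.random.default_rng(0)
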