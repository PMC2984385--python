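import numpy as np
import pytest

from ldlmap.simdesign import Scenario, simulate_design


@pytest.fixture(scope="session")
def small_scenario():
    """A miniature mapping design: 8 markers over 8 cM, 3 sires x 10 progeny."""
    return Scenario(n_e=50, n_generations=20, n_sires=3, n_progeny=10,
                    n_markers=8, density_cM=1.0, qtl_effect=0.5,
                    qtl_position_cM=3.6, seed=11)


@pytest.fixture(scope="session")
def small_design(small_scenario):
    return simulate_design(small_scenario, np.random.default_rng(11))


@pytest.fixture(scope="session")
def medium_design():
    """10 sires x 40 progeny on a 10-marker map, strong QTL."""
    scn = Scenario(n_e=80, n_generations=30, n_sires=10, n_progeny=40,
                   n_markers=10, density_cM=1.0, qtl_effect=0.5,
                   qtl_position_cM=4.6)
    return simulate_design(scn, np.random.default_rng(5))
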