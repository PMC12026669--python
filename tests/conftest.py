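import numpy as np
import pytest

from kinchain import panel as pn
from kinchain import sim as sm

PANEL_SEED = 42


@pytest.fixture(scope="session")
def default_panel():
    return pn.generate_panel(PANEL_SEED)


@pytest.fixture(scope="session")
def simulator(default_panel):
    panel, freqs = default_panel
    return sm.PedigreeSimulator(panel, freqs)


@pytest.fixture(scope="session")
def mutation_free_simulator(default_panel):
    panel, freqs = default_panel
    return sm.PedigreeSimulator(panel, freqs, str_mutation_rate=0.0,
                                snp_mutation_rate=0.0)


def make_tiny_panel(seed=0, n_a_str=4, n_a_snp=3, n_x=3, n_y=3):
    """A hand-sized panel for fast, precise unit tests."""
    spec = pn.PanelSpec(n_a_str=n_a_str, n_a_snp=n_a_snp, n_x_str=n_x,
                        n_y_str=n_y, y_pool_size=20, mt_pool_size=20,
                        mt_sites=12)
    return pn.generate_panel(seed, spec)


@pytest.fixture()
def tiny_panel():
    return make_tiny_panel()
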