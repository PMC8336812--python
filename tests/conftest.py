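import numpy as np
import pytest

from distreg.synthetic import SyntheticConfig, generate_lattice_districts, generate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A reduced two-wave synthetic survey shared across tests."""
    cfg = SyntheticConfig(seed=42, n_children={"2007": 400, "2013/14": 600})
    table, truth = generate_survey(cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def lattice5():
    graph, polys = generate_lattice_districts(5)
    return graph, polys


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
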