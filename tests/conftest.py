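import numpy as np
import pytest

from steppeadmix import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """400 autosomal SNPs + X, evenly spaced — enough blocks for jackknifes."""
    return sim.make_panel(400, seed=3)


@pytest.fixture(scope="session")
def graph_freqs(small_panel):
    return sim.simulate_graph(small_panel, sim.DEFAULT_GRAPH_EDGES, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
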