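import numpy as np
import pytest

from netres import Mutualistic, RandomInput, WeightedDigraph
from netres.workbench import NetworkRecipe, generate_network

#: Homogeneous mutualistic parameter set used throughout the suite.
PRINTED = dict(B=0.1, C=1.0, K=5.0, D=5.0, E=0.9, H=0.1)


@pytest.fixture
def printed_params():
    return dict(PRINTED)


@pytest.fixture
def mutualistic():
    return Mutualistic(params=dict(PRINTED))


def make_uncertain_mutualistic(mode="shared"):
    """C and E with uniform +-10% uncertainty around the printed means."""
    params = dict(PRINTED)
    params["C"] = RandomInput.uniform(0.9, 1.1, "C")
    params["E"] = RandomInput.uniform(0.81, 0.99, "E")
    return Mutualistic(params=params, mode=mode)


@pytest.fixture
def uncertain_mutualistic():
    return make_uncertain_mutualistic("shared")


@pytest.fixture
def uniform_graph():
    """Two nodes mutually coupled with weight w_av each."""
    def factory(w_av, n=2):
        M = np.full((n, n), w_av / max(n - 1, 1))
        np.fill_diagonal(M, 0.0)
        return WeightedDigraph(M)
    return factory


@pytest.fixture(scope="session")
def er_graph():
    """Seeded Erdos-Renyi digraph, N=100, scaled to w_av = 6.9."""
    recipe = NetworkRecipe("erdos-renyi", 100, density=0.15, seed=1,
                           target_w_av=6.9)
    return generate_network(recipe)


def weak_node_graph():
    """Seeded graph at w_av = 6.9 whose node 0 sits near its critical weight.

    Node 0's in-weight is rescaled to 0.25, close to where its reduced
    dynamics loses resilience, so its probability is strictly inside (0, 1)
    under the +-10% C/E uncertainty.
    """
    base = generate_network(NetworkRecipe("erdos-renyi", 60, density=0.2,
                                          seed=7, target_w_av=6.9))
    M = base.M.copy()
    M[:, 0] *= 0.25 / base.w_in[0]
    return WeightedDigraph(M)


@pytest.fixture(scope="session")
def case_a_graph():
    return weak_node_graph()
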