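import numpy as np
import pytest

import metapopgames as mg

UNIT_RPS = [[0, 1, -1], [-1, 0, 1], [1, -1, 0]]

# Three-patch migration cycle whose thermodynamic equilibrium is
# z* = (1/5, 2/5, 2/5): edges (1->2), (2->3), (3->1) with rates
# recovered from kappa = (1/10, 3/10, 1/10) via A[j,k] = kappa/z*_j.
CYCLE_EDGES = [
    (1, 2, 0.5, 0.25),
    (2, 3, 0.75, 0.75),
    (3, 1, 0.25, 0.5),
]

# Hub-and-spokes graph (no 2<->3 edge), unit rates: homogeneous.
STAR_EDGES = [
    (3, 1, 1.0, 1.0),
    (1, 2, 1.0, 1.0),
]


@pytest.fixture(scope="session")
def unit_rps():
    return mg.validate_tournament(UNIT_RPS)


@pytest.fixture(scope="session")
def cycle_graph():
    return mg.build_graph(CYCLE_EDGES)


@pytest.fixture(scope="session")
def star_graph():
    return mg.build_graph(STAR_EDGES)


@pytest.fixture(scope="session")
def heterogeneous_model(unit_rps, cycle_graph):
    return mg.assemble(unit_rps, cycle_graph)


@pytest.fixture(scope="session")
def homogeneous_model(unit_rps, star_graph):
    return mg.assemble(unit_rps, star_graph)
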