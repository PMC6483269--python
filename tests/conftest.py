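import pytest

from evopaths.fixtures import cycle_graph, standard_path_graph, valley_graph


@pytest.fixture
def path4():
    """4-vertex path graph with the standard rates (nu = 0.05)."""
    return standard_path_graph(0.05)


@pytest.fixture
def valley():
    """Two-path fitness-valley system (indirect path through lam(2) = -0.2)."""
    return valley_graph()


@pytest.fixture
def cyclic():
    """Four-vertex system with a 2<->3 cycle."""
    return cycle_graph()
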