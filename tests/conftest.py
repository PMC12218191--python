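import pytest

from econet import SpatialGraph
from econet.synth import geometric_graph, uniform_points


@pytest.fixture
def triangle_graph():
    """3 collinear equispaced points with the two short edges present."""
    return SpatialGraph.from_edges(
        {"a": [0.0], "b": [1.0], "c": [2.0]},
        [("a", "b", 1.0), ("b", "c", 1.0)],
    )


@pytest.fixture
def complete_k4():
    coords = {str(k): p for k, p in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)])}
    edges = [
        (str(i), str(j), float(i + j + 1))
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    return SpatialGraph.from_edges(coords, edges)


@pytest.fixture(scope="session")
def random_regime_graph():
    """Complete 40-node graph with weights independent of lengths."""
    return geometric_graph(uniform_points(40, seed=10), regime="random", seed=11)


@pytest.fixture(scope="session")
def short_regime_graph():
    """Complete 40-node graph whose weights strictly decrease with length."""
    return geometric_graph(uniform_points(40, seed=12), regime="short", seed=13)
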