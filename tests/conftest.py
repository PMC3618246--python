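import numpy as np
import pytest

from tnmca.synthgen import (
    abc_fixture,
    four_cycle_fixture,
    near_match_fixture,
    triangle_fixture,
)
from tnmca.typed_graph import TypedGraph


@pytest.fixture
def triangle_graph() -> TypedGraph:
    return triangle_fixture()


@pytest.fixture
def four_cycle_graph() -> TypedGraph:
    return four_cycle_fixture()


@pytest.fixture
def near_match_graph() -> TypedGraph:
    return near_match_fixture()


@pytest.fixture
def abc_graph() -> TypedGraph:
    return abc_fixture()


@pytest.fixture
def path_graph() -> TypedGraph:
    g = TypedGraph()
    g.add_node("a", "chemical")
    g.add_node("b", "gene")
    g.add_node("c", "disease")
    g.add_edge("a", "b", "increases")
    g.add_edge("b", "c", "marker")
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
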