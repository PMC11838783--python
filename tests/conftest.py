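import numpy as np
import pytest

from pathcurv.graphs import PathwayGraph, generate_synthetic
from pathcurv.manifolds import Component, EUCLIDEAN, HYPERBOLIC, SPHERICAL


@pytest.fixture
def triangle() -> PathwayGraph:
    return PathwayGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> PathwayGraph:
    return PathwayGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def tree31() -> PathwayGraph:
    return generate_synthetic("balanced_tree", {"branching": 2, "depth": 4})


@pytest.fixture
def cycle20() -> PathwayGraph:
    return generate_synthetic("cycle", {"n": 20})


@pytest.fixture(
    params=[
        (SPHERICAL, 0.5),
        (SPHERICAL, 1.0),
        (SPHERICAL, 2.0),
        (HYPERBOLIC, 0.5),
        (HYPERBOLIC, 1.0),
        (HYPERBOLIC, 2.0),
        (EUCLIDEAN, 1.0),
    ],
    ids=lambda p: f"{p[0][0].upper()}-C{p[1]}",
)
def component3(request) -> Component:
    space, curv = request.param
    return Component(space, 3, curv)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
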