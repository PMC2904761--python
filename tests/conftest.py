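import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pathgrid import (
    CompartmentSpec,
    ConstraintMap,
    CostParams,
    Grid,
    Layout,
    PathwayGraph,
    PathwayNode,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def triangle_graph():
    nodes = [PathwayNode(i, localization="cytoplasm") for i in "abc"]
    return PathwayGraph(nodes, [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path_graph():
    nodes = [PathwayNode(i, localization="cytoplasm") for i in "abc"]
    return PathwayGraph(nodes, [("a", "b"), ("b", "c")])


@pytest.fixture
def open_grid():
    return Grid(6, 6)


@pytest.fixture
def open_cm(open_grid):
    return ConstraintMap.unconstrained(open_grid, {"cytoplasm"})


def make_scene(grid: Grid):
    """Two disjoint rectangle compartments on the left/right grid halves."""
    half = grid.w // 2
    left = CompartmentSpec(
        id="left", shape="rectangle",
        center=((grid.h - 1) / 2, (half - 1) / 2),
        size=(float(grid.h), float(half)), tags=("cytoplasm",),
    )
    right = CompartmentSpec(
        id="right", shape="rectangle",
        center=((grid.h - 1) / 2, half + (grid.w - half - 1) / 2),
        size=(float(grid.h), float(grid.w - half)), tags=("nucleus",),
    )
    return [left, right]
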