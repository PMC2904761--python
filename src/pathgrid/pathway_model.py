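"""Core domain types for pathway grid layout.

A pathway is an undirected graph whose nodes carry a sub-cellular
localization tag (``cytoplasm``, ``nucleus``, ``plasma_membrane``, ...).
A layout maps every node to a distinct point of an integer grid of
``h`` rows by ``w`` columns.  Compartments are geometric regions of the
grid (rectangles, ovals, or rectangular annuli modelling membranes);
the set of compartments carrying a given tag induces the set of grid
points a node with that tag may occupy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

#: Localization vocabulary bundled with the package.  Tags are free
#: strings; these are merely the names used by the default scene.
KNOWN_TAGS = (
    "extracellular",
    "plasma_membrane",
    "cytoplasm",
    "nuclear_membrane",
    "nucleus",
    "mitochondria",
    "golgi",
)

GridPoint = tuple[int, int]


class GraphError(ValueError):
    """Raised for structurally invalid pathway graphs."""


class ConfigurationError(ValueError):
    """Raised for invalid compartment / constraint configuration."""


class LayoutError(ValueError):
    """Raised when a layout violates its preconditions."""


@dataclass(frozen=True)
class PathwayNode:
    id: str
    label: str = ""
    localization: str = "cytoplasm"


class PathwayGraph:
    """Undirected pathway graph with localization-tagged nodes.

    Invariants enforced on construction: unique node ids, edge
    endpoints exist, no self-loops, no duplicate (unordered) edges.
    """

    def __init__(self, nodes: Iterable[PathwayNode], edges: Iterable[Sequence[str]]):
        self.nodes: list[PathwayNode] = list(nodes)
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphError(f"duplicate node ids: {dupes}")
        self._by_id = {n.id: n for n in self.nodes}
        self.edges: list[tuple[str, str]] = []
        seen: set[frozenset[str]] = set()
        for e in edges:
            a, b = e
            if a not in self._by_id or b not in self._by_id:
                raise GraphError(f"edge ({a!r}, {b!r}) references unknown node")
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise GraphError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)
            self.edges.append((a, b))
        self._adj: dict[str, list[str]] = {n.id: [] for n in self.nodes}
        for a, b in self.edges:
            self._adj[a].append(b)
            self._adj[b].append(a)

    # -- accessors ---------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node(self, node_id: str) -> PathwayNode:
        return self._by_id[node_id]

    def neighbors(self, node_id: str) -> list[str]:
        return list(self._adj[node_id])

    def degree(self, node_id: str) -> int:
        return len(self._adj[node_id])

    def localization(self, node_id: str) -> str:
        return self._by_id[node_id].localization

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._by_id

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PathwayGraph(|V|={self.n_nodes}, |E|={self.n_edges})"


@dataclass(frozen=True)
class Grid:
    """Integer lattice of ``h`` rows by ``w`` columns, 0-based (row, col)."""

    h: int
    w: int

    def __post_init__(self):
        if self.h < 1 or self.w < 1:
            raise ConfigurationError(f"grid must be at least 1x1, got {self.h}x{self.w}")

    @property
    def n_points(self) -> int:
        return self.h * self.w

    def contains(self, p: GridPoint) -> bool:
        return 0 <= p[0] < self.h and 0 <= p[1] < self.w

    def points(self) -> Iterable[GridPoint]:
        for r in range(self.h):
            for c in range(self.w):
                yield (r, c)


class Layout:
    """Injective, total assignment of node ids to grid points."""

    def __init__(self, assignment: Mapping[str, GridPoint]):
        self.assignment: dict[str, GridPoint] = {
            k: (int(v[0]), int(v[1])) for k, v in assignment.items()
        }

    def __getitem__(self, node_id: str) -> GridPoint:
        return self.assignment[node_id]

    def __setitem__(self, node_id: str, p: GridPoint) -> None:
        self.assignment[node_id] = (int(p[0]), int(p[1]))

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.assignment

    def __eq__(self, other) -> bool:
        return isinstance(other, Layout) and self.assignment == other.assignment

    def __len__(self) -> int:
        return len(self.assignment)

    def items(self):
        return self.assignment.items()

    def copy(self) -> "Layout":
        return Layout(self.assignment)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Layout({len(self.assignment)} nodes)"


# boundary-tie tolerance for real-valued region membership
_EPS = 1e-9


@dataclass
class CompartmentSpec:
    """Geometric compartment bound to one or more localization tags.

    ``center`` is (row, col), real-valued; ``size`` is (height, width)
    in grid units.  ``annulus`` compartments are rectangular frames:
    the outer rectangle minus the inner rectangle including the inner
    boundary (a point on the inner boundary belongs to the inside, not
    the ring).  ``container`` optionally names the compartment this one
    must remain geometrically inside of; ancestors are exempt from the
    mutual-overlap test used during dynamic compartment updates.
    """

    id: str
    shape: str  # rectangle | oval | annulus
    center: tuple[float, float]
    size: tuple[float, float]
    inner_size: tuple[float, float] | None = None
    movable: bool = False
    tags: tuple[str, ...] = ()
    container: str | None = None
    original_size: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.shape not in ("rectangle", "oval", "annulus"):
            raise ConfigurationError(f"unknown compartment shape {self.shape!r}")
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ConfigurationError(f"compartment {self.id!r} has non-positive size")
        if self.shape == "annulus":
            if self.inner_size is None:
                raise ConfigurationError(f"annulus {self.id!r} needs inner_size")
            if not (self.inner_size[0] < self.size[0] and self.inner_size[1] < self.size[1]):
                raise ConfigurationError(
                    f"annulus {self.id!r}: inner size must be strictly inside outer size"
                )
        self.center = (float(self.center[0]), float(self.center[1]))
        self.size = (float(self.size[0]), float(self.size[1]))
        self.tags = tuple(self.tags)
        if self.original_size is None:
            self.original_size = self.size

    # -- geometry ----------------------------------------------------
    def _in_rect(self, r, c, size) -> np.ndarray | bool:
        hh, hw = size[0] / 2.0, size[1] / 2.0
        return (np.abs(r - self.center[0]) <= hh + _EPS) & (
            np.abs(c - self.center[1]) <= hw + _EPS
        )

    def membership(self, r, c):
        """Vectorized point-in-region test; boundary ties count inside."""
        if self.shape == "rectangle":
            return self._in_rect(r, c, self.size)
        if self.shape == "oval":
            a, b = self.size[0] / 2.0, self.size[1] / 2.0
            return ((r - self.center[0]) / a) ** 2 + ((c - self.center[1]) / b) ** 2 <= 1 + _EPS
        # annulus: outer rectangle minus inner rectangle (inner boundary
        # belongs to the inside, hence excluded from the ring)
        return self._in_rect(r, c, self.size) & ~self._in_rect(r, c, self.inner_size)

    def contains(self, p: Sequence[float]) -> bool:
        return bool(self.membership(float(p[0]), float(p[1])))

    def mask(self, grid: Grid) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(grid.h), np.arange(grid.w), indexing="ij")
        return np.asarray(self.membership(rr.astype(float), cc.astype(float)), dtype=bool)

    def bounding_rect(self) -> tuple[float, float, float, float]:
        """(rmin, rmax, cmin, cmax) of the bounding rectangle."""
        return (
            self.center[0] - self.size[0] / 2.0,
            self.center[0] + self.size[0] / 2.0,
            self.center[1] - self.size[1] / 2.0,
            self.center[1] + self.size[1] / 2.0,
        )

    def scaled(self, factor: float) -> "CompartmentSpec":
        inner = None
        if self.inner_size is not None:
            inner = (self.inner_size[0] * factor, self.inner_size[1] * factor)
        return replace(
            self,
            size=(self.size[0] * factor, self.size[1] * factor),
            inner_size=inner,
            original_size=self.original_size,
        )

    def with_center(self, center: Sequence[float]) -> "CompartmentSpec":
        return replace(self, center=(float(center[0]), float(center[1])),
                       original_size=self.original_size)


def rects_overlap_corner_test(a: CompartmentSpec, b: CompartmentSpec) -> bool:
    """Bounding-rectangle overlap via the corner-in-rectangle test.

    Checks whether a corner of one rectangle lies in the other (both
    directions).  This test has a known false negative for cross-shaped
    overlap where no corner of either rectangle is inside the other;
    it is kept as the default for fidelity, with
    :func:`rects_overlap_strict` as the exact alternative.
    """
    ar0, ar1, ac0, ac1 = a.bounding_rect()
    br0, br1, bc0, bc1 = b.bounding_rect()

    def corner_in(r, c, r0, r1, c0, c1):
        return r0 - _EPS <= r <= r1 + _EPS and c0 - _EPS <= c <= c1 + _EPS

    for r, c in ((ar0, ac0), (ar0, ac1), (ar1, ac0), (ar1, ac1)):
        if corner_in(r, c, br0, br1, bc0, bc1):
            return True
    for r, c in ((br0, bc0), (br0, bc1), (br1, bc0), (br1, bc1)):
        if corner_in(r, c, ar0, ar1, ac0, ac1):
            return True
    return False


def rects_overlap_strict(a: CompartmentSpec, b: CompartmentSpec) -> bool:
    """Exact bounding-rectangle intersection test."""
    ar0, ar1, ac0, ac1 = a.bounding_rect()
    br0, br1, bc0, bc1 = b.bounding_rect()
    return (ar0 <= br1 + _EPS and br0 <= ar1 + _EPS
            and ac0 <= bc1 + _EPS and bc0 <= ac1 + _EPS)


def rect_inside_rect(inner: CompartmentSpec, outer: CompartmentSpec) -> bool:
    ir0, ir1, ic0, ic1 = inner.bounding_rect()
    or0, or1, oc0, oc1 = outer.bounding_rect()
    return (or0 - _EPS <= ir0 and ir1 <= or1 + _EPS
            and oc0 - _EPS <= ic0 and ic1 <= oc1 + _EPS)


def region_points(
    compartments: Sequence[CompartmentSpec], tag: str, grid: Grid
) -> set[GridPoint]:
    """All grid points admissible for ``tag`` (union over its compartments)."""
    relevant = [c for c in compartments if tag in c.tags]
    if not relevant:
        raise ConfigurationError(f"no compartment carries localization tag {tag!r}")
    mask = np.zeros((grid.h, grid.w), dtype=bool)
    for comp in relevant:
        mask |= comp.mask(grid)
    rr, cc = np.nonzero(mask)
    return {(int(r), int(c)) for r, c in zip(rr, cc)}


class ConstraintMap:
    """Per-tag admissible grid points derived from a compartment scene.

    For an unconstrained run (the "NL" mode) every tag maps to the full
    grid and the compartment list is empty.
    """

    def __init__(
        self,
        grid: Grid,
        tag_masks: dict[str, np.ndarray],
        compartments: Sequence[CompartmentSpec] = (),
    ):
        self.grid = grid
        self.tag_masks = tag_masks
        self.compartments = list(compartments)
        for tag, m in tag_masks.items():
            if not m.any():
                raise ConfigurationError(f"admissible region for tag {tag!r} is empty")

    @classmethod
    def from_compartments(
        cls,
        compartments: Sequence[CompartmentSpec],
        grid: Grid,
        tags: Iterable[str] | None = None,
    ) -> "ConstraintMap":
        if tags is None:
            tags = sorted({t for c in compartments for t in c.tags})
        masks: dict[str, np.ndarray] = {}
        for tag in tags:
            relevant = [c for c in compartments if tag in c.tags]
            if not relevant:
                raise ConfigurationError(f"no compartment carries localization tag {tag!r}")
            m = np.zeros((grid.h, grid.w), dtype=bool)
            for comp in relevant:
                m |= comp.mask(grid)
            masks[tag] = m
        return cls(grid, masks, compartments)

    @classmethod
    def unconstrained(cls, grid: Grid, tags: Iterable[str] = ()) -> "ConstraintMap":
        full = np.ones((grid.h, grid.w), dtype=bool)
        masks = {tag: full for tag in tags}
        cm = cls(grid, masks, [])
        cm._default_full = True
        return cm

    def mask_for(self, tag: str) -> np.ndarray:
        if tag in self.tag_masks:
            return self.tag_masks[tag]
        if getattr(self, "_default_full", False):
            return np.ones((self.grid.h, self.grid.w), dtype=bool)
        raise ConfigurationError(f"unknown localization tag {tag!r}")

    def points_for(self, tag: str) -> set[GridPoint]:
        m = self.mask_for(tag)
        rr, cc = np.nonzero(m)
        return {(int(r), int(c)) for r, c in zip(rr, cc)}

    def admits(self, tag: str, p: GridPoint) -> bool:
        return self.grid.contains(p) and bool(self.mask_for(tag)[p])

    def nodes_in_compartment(self, graph: PathwayGraph, comp: CompartmentSpec) -> list[str]:
        """V_c: node ids localized to compartment ``comp`` (by tag)."""
        return [n.id for n in graph.nodes if n.localization in comp.tags]


@dataclass
class Violation:
    kind: str  # "collision" | "constraint" | "off_grid" | "missing"
    nodes: tuple[str, ...]
    point: GridPoint | None
    message: str


def validate_layout(
    graph: PathwayGraph, layout: Layout, constraints: ConstraintMap
) -> list[Violation]:
    """Return violations (empty iff layout is injective and admissible).

    Violations are data, not exceptions: callers decide what is fatal.
    """
    out: list[Violation] = []
    occupied: dict[GridPoint, str] = {}
    for node in graph.nodes:
        if node.id not in layout:
            out.append(Violation("missing", (node.id,), None, f"node {node.id!r} unplaced"))
            continue
        p = layout[node.id]
        if not constraints.grid.contains(p):
            out.append(Violation("off_grid", (node.id,), p, f"{node.id!r} at {p} off-grid"))
            continue
        if p in occupied:
            out.append(
                Violation(
                    "collision", (occupied[p], node.id), p,
                    f"nodes {occupied[p]!r} and {node.id!r} share grid point {p}",
                )
            )
        else:
            occupied[p] = node.id
        if not constraints.admits(node.localization, p):
            out.append(
                Violation(
                    "constraint", (node.id,), p,
                    f"{node.id!r} ({node.localization}) at {p} outside its admissible region",
                )
            )
    return out


def euclidean(p: Sequence[float], q: Sequence[float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _default_attraction(d):
    return np.asarray(d, dtype=float) ** 2


def _default_repulsion(d):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        out = 1.0 / (d * d)
    return out


@dataclass
class CostParams:
    """Weights and force functions of the layout cost.

    ``w_n`` defaults to twice ``w_e`` (node-edge crossings obscure
    connectivity more than edge-edge crossings do).  ``alpha`` defaults
    to ``20 * (w + h)`` of the grid it is applied to and scales the
    compartment-surface penalty ``alpha * exp(-beta * l)`` used by the
    dynamic-compartment mode.
    """

    w_a: float = 1.0
    w_r: float = 1.0
    w_e: float = 10.0
    w_n: float | None = None
    alpha: float | None = None
    beta: float = 0.002
    F_a: Callable = field(default=_default_attraction)
    F_r: Callable = field(default=_default_repulsion)

    def __post_init__(self):
        if self.w_n is None:
            self.w_n = 2.0 * self.w_e
        for name in ("w_a", "w_r", "w_e", "w_n"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")

    def resolved_alpha(self, grid: Grid) -> float:
        return float(self.alpha) if self.alpha is not None else 20.0 * (grid.w + grid.h)

    # Named presets from the three study pathways.
    @classmethod
    def fas(cls) -> "CostParams":
        return cls(w_a=1, w_r=1, w_e=10, w_n=20)

    @classmethod
    def elegans(cls) -> "CostParams":
        return cls(w_a=1, w_r=1, w_e=50, w_n=100)

    @classmethod
    def endothelial(cls) -> "CostParams":
        return cls(w_a=12, w_r=1, w_e=50, w_n=100)


PRESETS = {
    "fas": CostParams.fas,
    "elegans": CostParams.elegans,
    "endothelial": CostParams.endothelial,
}
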