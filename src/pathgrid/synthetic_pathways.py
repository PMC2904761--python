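"""Synthetic annotated pathway generator.

Produces sparse, scale-free-ish pathway graphs with localization tags
plus a default compartment scene, at the scales of typical curated
signalling models (tens to a couple of hundred nodes, average degree
around 2.2-2.5), so the whole package is testable without downloads.

The grid sizing helper follows the empirical rule that rows + columns
should grow proportionally to sqrt(|V|); the default ratio of 8 sits
inside the 6.5-11 band observed across the curated study models.
"""

from __future__ import annotations

import math

import numpy as np

from .pathway_model import (
    CompartmentSpec,
    ConfigurationError,
    ConstraintMap,
    Grid,
    Layout,
    PathwayGraph,
    PathwayNode,
)

#: Default localization mixture for generated pathways; weighted toward
#: the cytoplasm like most curated signalling models.
DEFAULT_MIX = {
    "extracellular": 0.05,
    "plasma_membrane": 0.15,
    "cytoplasm": 0.50,
    "nucleus": 0.20,
    "mitochondria": 0.10,
}

SIZING_RATIO = 8.0


def sizing_ratio(h: int, w: int, n_nodes: int) -> float:
    """(rows + columns) / sqrt(|V|) — the grid-sizing rule statistic."""
    return (h + w) / math.sqrt(n_nodes)


def grid_for_nodes(n_nodes: int, ratio: float = SIZING_RATIO) -> Grid:
    """Near-square grid with (h + w) ~= ratio * sqrt(|V|)."""
    side = max(8, int(round(ratio * math.sqrt(n_nodes) / 2.0)))
    return Grid(side, side)


def default_compartments(grid: Grid) -> list[CompartmentSpec]:
    """Canonical cell scene: extracellular rim, plasma-membrane frame,
    cytoplasm, movable nucleus and mitochondria ovals.

    The extracellular space and the membrane are rectangular annuli
    (the membrane frame is one grid unit thick); the nucleus and
    mitochondria are nested inside the cytoplasm via ``container`` so
    the dynamic-update overlap test applies between siblings only.
    """
    h, w = grid.h, grid.w
    if h < 14 or w < 14:
        raise ConfigurationError("default scene needs a grid of at least 14x14")
    cr, cc_ = (h - 1) / 2.0, (w - 1) / 2.0
    cell_outer = (h - 4.0, w - 4.0)
    cell_inner = (h - 6.0, w - 6.0)
    comps = [
        CompartmentSpec(
            id="extracellular", shape="annulus", center=(cr, cc_),
            size=(float(h), float(w)), inner_size=cell_outer,
            movable=False, tags=("extracellular",),
        ),
        CompartmentSpec(
            id="plasma_membrane", shape="annulus", center=(cr, cc_),
            size=cell_outer, inner_size=cell_inner,
            movable=False, tags=("plasma_membrane",), container="extracellular",
        ),
        CompartmentSpec(
            id="cytoplasm", shape="rectangle", center=(cr, cc_),
            size=cell_inner, movable=False, tags=("cytoplasm",),
            container="plasma_membrane",
        ),
        CompartmentSpec(
            id="nucleus", shape="oval",
            center=(cr, cc_ + 0.22 * w),
            size=(0.42 * cell_inner[0], 0.36 * cell_inner[1]),
            movable=True, tags=("nucleus",), container="cytoplasm",
        ),
        CompartmentSpec(
            id="mitochondria", shape="oval",
            center=(cr - 0.18 * h, cc_ - 0.2 * w),
            size=(0.3 * cell_inner[0], 0.28 * cell_inner[1]),
            movable=True, tags=("mitochondria",), container="cytoplasm",
        ),
    ]
    return comps


def generate_pathway(
    n_nodes: int,
    n_edges: int,
    localization_mix: dict[str, float] | None = None,
    seed: int = 0,
    grid: Grid | None = None,
) -> tuple[PathwayGraph, list[CompartmentSpec]]:
    """Random annotated pathway plus the default compartment scene.

    Topology is preferential attachment: a random recursive tree with
    degree-proportional attachment, then extra degree-biased edges up
    to exactly ``n_edges`` — sparse, connected, heavy-tailed degrees.
    """
    if n_nodes < 2:
        raise ConfigurationError("need at least 2 nodes")
    if n_edges < n_nodes - 1:
        raise ConfigurationError("need at least n_nodes - 1 edges for connectivity")
    mix = dict(DEFAULT_MIX if localization_mix is None else localization_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigurationError("localization mix must sum to 1")
    rng = np.random.default_rng(seed)

    deg = np.zeros(n_nodes, dtype=float)
    edges: list[tuple[int, int]] = []
    seen: set[frozenset[int]] = set()
    for v in range(1, n_nodes):
        weights = deg[:v] + 1.0
        u = int(rng.choice(v, p=weights / weights.sum()))
        edges.append((u, v))
        seen.add(frozenset((u, v)))
        deg[u] += 1
        deg[v] += 1
    tries = 0
    while len(edges) < n_edges and tries < 50 * n_edges:
        tries += 1
        weights = deg + 1.0
        u, v = rng.choice(n_nodes, size=2, p=weights / weights.sum())
        u, v = int(u), int(v)
        if u == v or frozenset((u, v)) in seen:
            continue
        edges.append((u, v))
        seen.add(frozenset((u, v)))
        deg[u] += 1
        deg[v] += 1
    if len(edges) < n_edges:
        raise ConfigurationError("could not place the requested number of edges")

    tags = list(mix)
    probs = np.array([mix[t] for t in tags], dtype=float)
    assigned = rng.choice(len(tags), size=n_nodes, p=probs)
    width = len(str(n_nodes - 1))
    nodes = [
        PathwayNode(
            id=f"n{i:0{width}d}",
            label=f"mol_{i:0{width}d}",
            localization=tags[assigned[i]],
        )
        for i in range(n_nodes)
    ]
    graph = PathwayGraph(
        nodes, [(nodes[a].id, nodes[b].id) for a, b in edges]
    )
    if grid is None:
        grid = grid_for_nodes(n_nodes)
    return graph, default_compartments(grid)


def random_layout(
    graph: PathwayGraph,
    grid: Grid,
    constraints: ConstraintMap,
    seed: int = 0,
    max_tries: int = 50,
) -> Layout:
    """Seeded random admissible injective layout.

    Nodes are placed in random order, each uniformly over its still
    vacant admissible points; rare dead ends (overlapping regions
    exhausted out of order) restart the draw.
    """
    ids = sorted(graph.node_ids)
    by_tag: dict[str, list[str]] = {}
    for nid in ids:
        by_tag.setdefault(graph.localization(nid), []).append(nid)
    for tag, members in by_tag.items():
        cap = int(constraints.mask_for(tag).sum())
        if cap < len(members):
            raise ConfigurationError(
                f"tag {tag!r}: {len(members)} nodes but only {cap} admissible points"
            )
    rng = np.random.default_rng(seed)
    w = grid.w
    for _ in range(max_tries):
        occupied = np.zeros((grid.h, grid.w), dtype=bool)
        assignment: dict[str, tuple[int, int]] = {}
        order = rng.permutation(len(ids))
        ok = True
        for k in order:
            nid = ids[int(k)]
            mask = constraints.mask_for(graph.localization(nid)) & ~occupied
            flat = np.nonzero(mask.ravel())[0]
            if flat.size == 0:
                ok = False
                break
            choice = int(flat[rng.integers(flat.size)])
            p = divmod(choice, w)
            assignment[nid] = p
            occupied[p] = True
        if ok:
            return Layout(assignment)
    raise ConfigurationError("could not draw an admissible random layout")
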