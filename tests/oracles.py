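"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — rational-arithmetic geometry,
O(n^2) pairwise loops, exhaustive enumeration — and shares no code
path with the package's fast backends.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# rational-arithmetic segment geometry
# ---------------------------------------------------------------------------

def segments_cross_frac(e, f) -> int:
    """Interior-intersection of two segments via exact line solving."""
    (x1, y1), (x2, y2) = ((Fraction(p[0]), Fraction(p[1])) for p in e)
    (x3, y3), (x4, y4) = ((Fraction(p[0]), Fraction(p[1])) for p in f)
    d1 = (x2 - x1, y2 - y1)
    d2 = (x4 - x3, y4 - y3)
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if denom != 0:
        # solve e1 + t*d1 == f1 + s*d2 ; interior crossing iff 0<t<1, 0<s<1
        t = ((x3 - x1) * d2[1] - (y3 - y1) * d2[0]) / denom
        s = ((x3 - x1) * d1[1] - (y3 - y1) * d1[0]) / denom
        return 1 if 0 < t < 1 and 0 < s < 1 else 0
    # parallel: collinear iff f1 lies on the line of e
    if (x3 - x1) * d1[1] - (y3 - y1) * d1[0] != 0:
        return 0
    # collinear: open parameter intervals along e must overlap
    L = d1[0] * d1[0] + d1[1] * d1[1]

    def param(px, py):
        return (px - x1) * d1[0] + (py - y1) * d1[1]

    t3, t4 = param(x3, y3), param(x4, y4)
    lo, hi = min(t3, t4), max(t3, t4)
    return 1 if max(lo, 0) < min(hi, L) else 0


def node_on_edge_frac(p, e) -> int:
    (px, py) = Fraction(p[0]), Fraction(p[1])
    (x1, y1), (x2, y2) = ((Fraction(q[0]), Fraction(q[1])) for q in e)
    if (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1) != 0:
        return 0
    dot = (px - x1) * (px - x2) + (py - y1) * (py - y2)
    return 1 if dot < 0 else 0


def count_crossings_brute(graph, positions) -> tuple[int, int]:
    edges = graph.edges
    ee = 0
    for i in range(len(edges)):
        a, b = edges[i]
        for j in range(i + 1, len(edges)):
            c, d = edges[j]
            if len({a, b, c, d}) < 4:
                continue
            ee += segments_cross_frac(
                (positions[a], positions[b]), (positions[c], positions[d])
            )
    ne = 0
    for nid in graph.node_ids:
        for a, b in edges:
            if nid in (a, b):
                continue
            ne += node_on_edge_frac(positions[nid], (positions[a], positions[b]))
    return ee, ne


# ---------------------------------------------------------------------------
# naive cost components
# ---------------------------------------------------------------------------

def attraction_brute(graph, positions, F_a=lambda d: d * d) -> float:
    total = 0.0
    for a, b in graph.edges:
        d = math.dist(positions[a], positions[b])
        total += F_a(d)
    return total


def repulsion_brute(graph, positions, F_r=lambda d: 1.0 / (d * d)) -> float:
    ids = graph.node_ids
    total = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = math.dist(positions[ids[i]], positions[ids[j]])
            total += F_r(d)
    return total


def total_cost_brute(graph, positions, params) -> float:
    ee, ne = count_crossings_brute(graph, positions)
    return (
        params.w_a * attraction_brute(graph, positions)
        + params.w_r * repulsion_brute(graph, positions)
        + params.w_e * ee
        + params.w_n * ne
    )


def repulsion_field_brute(positions_list, grid, F_r=lambda d: 1.0 / (d * d)) -> np.ndarray:
    """Direct summation of F_r over nodes at every grid point (self-term 0)."""
    field = np.zeros((grid.h, grid.w))
    for r in range(grid.h):
        for c in range(grid.w):
            for (pr, pc) in positions_list:
                d2 = (r - pr) ** 2 + (c - pc) ** 2
                if d2 > 0:
                    field[r, c] += F_r(math.sqrt(d2))
    return field


# ---------------------------------------------------------------------------
# point-in-region brute force
# ---------------------------------------------------------------------------

def point_in_compartment_brute(comp, r, c, eps=1e-9) -> bool:
    cr, cc = comp.center

    def in_rect(size):
        return abs(r - cr) <= size[0] / 2 + eps and abs(c - cc) <= size[1] / 2 + eps

    if comp.shape == "rectangle":
        return in_rect(comp.size)
    if comp.shape == "oval":
        return ((r - cr) / (comp.size[0] / 2)) ** 2 + (
            (c - cc) / (comp.size[1] / 2)
        ) ** 2 <= 1 + eps
    return in_rect(comp.size) and not in_rect(comp.inner_size)


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_instance(rng, max_nodes=12, grid_side=8):
    """Small random graph + injective random layout on an open grid."""
    from pathgrid import ConstraintMap, Grid, Layout, PathwayGraph, PathwayNode

    n = int(rng.integers(2, max_nodes + 1))
    h = int(rng.integers(4, grid_side + 1))
    w = int(rng.integers(4, grid_side + 1))
    n = min(n, h * w - 1)
    ids = [f"x{i}" for i in range(n)]
    nodes = [PathwayNode(i, localization="cytoplasm") for i in ids]
    possible = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)]
    k = int(rng.integers(0, min(len(possible), 2 * n) + 1))
    chosen = rng.choice(len(possible), size=k, replace=False) if k else []
    graph = PathwayGraph(nodes, [possible[int(i)] for i in chosen])
    cells = [(r, c) for r in range(h) for c in range(w)]
    pick = rng.choice(len(cells), size=n, replace=False)
    layout = Layout({ids[i]: cells[int(pick[i])] for i in range(n)})
    grid = Grid(h, w)
    cm = ConstraintMap.unconstrained(grid, {"cytoplasm"})
    return graph, grid, cm, layout
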