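"""Exact crossing predicates and counters on the integer grid.

Conventions (they define what the cost function punishes):

* two edge segments "cross" iff their relative interiors intersect —
  proper transversal crossings and collinear overlaps count, shared
  endpoints and T-junctions do not;
* edge pairs sharing a *graph* endpoint are never counted;
* a node-edge crossing is a node lying strictly inside another edge's
  segment (endpoints excluded).

All predicates use integer cross-product arithmetic and are exact for
grid coordinates.  The same formulas applied to floats are used for
the continuous spring-embedder layouts, where generic positions make
degeneracies irrelevant.

The bulk counter returns, for one node, the edge-edge / node-edge
crossing change for a move to *every* grid point at once; it is the
package's fast backend and is oracle-tested against plain pairwise
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .pathway_model import Grid, GridPoint, Layout, PathwayGraph

Point = Sequence[float]
Seg = tuple[Point, Point]


# ---------------------------------------------------------------------------
# scalar predicates
# ---------------------------------------------------------------------------

def _orient(p: Point, q: Point, r: Point):
    """Signed area cross product of (q - p) x (r - p)."""
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def segments_cross(e: Seg, f: Seg) -> int:
    """1 iff the relative interiors of segments ``e`` and ``f`` intersect.

    Proper crossings and collinear overlaps return 1; touching at an
    endpoint (shared endpoint or T-junction) returns 0.
    """
    e1, e2 = e
    f1, f2 = f
    d1 = _orient(f1, f2, e1)
    d2 = _orient(f1, f2, e2)
    d3 = _orient(e1, e2, f1)
    d4 = _orient(e1, e2, f2)
    if d1 * d2 < 0 and d3 * d4 < 0:
        return 1
    if d1 == 0 and d2 == 0 and d3 == 0 and d4 == 0:
        # all four endpoints collinear: 1 iff open projections overlap
        dr, dc = e2[0] - e1[0], e2[1] - e1[1]
        length = dr * dr + dc * dc

        def t(p):
            return (p[0] - e1[0]) * dr + (p[1] - e1[1]) * dc

        tf1, tf2 = t(f1), t(f2)
        lo, hi = min(tf1, tf2), max(tf1, tf2)
        return 1 if max(lo, 0) < min(hi, length) else 0
    return 0


def node_on_edge(p: Point, e: Seg) -> int:
    """1 iff point ``p`` lies strictly inside segment ``e`` (endpoints excluded)."""
    e1, e2 = e
    if _orient(e1, e2, p) != 0:
        return 0
    dot = (p[0] - e1[0]) * (p[0] - e2[0]) + (p[1] - e1[1]) * (p[1] - e2[1])
    return 1 if dot < 0 else 0


def count_crossings_of_positions(
    graph: PathwayGraph, positions: Mapping[str, Point]
) -> tuple[int, int]:
    """Pairwise (edge-edge, node-edge) crossing counts for any position map."""
    edges = graph.edges
    ee = 0
    for i in range(len(edges)):
        a, b = edges[i]
        sa = (positions[a], positions[b])
        for j in range(i + 1, len(edges)):
            c, d = edges[j]
            if a in (c, d) or b in (c, d):
                continue  # shared graph endpoint
            ee += segments_cross(sa, (positions[c], positions[d]))
    ne = 0
    for node in graph.node_ids:
        p = positions[node]
        for a, b in edges:
            if node in (a, b):
                continue
            ne += node_on_edge(p, (positions[a], positions[b]))
    return ee, ne


def count_all_crossings(graph: PathwayGraph, layout: Layout) -> tuple[int, int]:
    """(edge-edge, node-edge) crossing counts of a grid layout."""
    return count_crossings_of_positions(graph, layout.assignment)


# ---------------------------------------------------------------------------
# vectorized candidate tables
# ---------------------------------------------------------------------------

# int32 is exact here for grids up to ~2^11 per side: orientation values
# are bounded by 2 * side^2 and only their signs are ever combined.
_MAX_SIDE = 2048


@lru_cache(maxsize=8)
def _mesh(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    if h > _MAX_SIDE or w > _MAX_SIDE:  # pragma: no cover - sanity bound
        raise ValueError(f"grid side exceeds supported bound {_MAX_SIDE}")
    rr, cc = np.meshgrid(np.arange(h, dtype=np.int32), np.arange(w, dtype=np.int32),
                         indexing="ij")
    return rr, cc


def _opp_sign(x, y):
    """Strictly opposite signs, product-free (overflow-safe)."""
    return ((x > 0) & (y < 0)) | ((x < 0) & (y > 0))


def _cross_moving(qr, qc, ar, ac, p3r, p3c, p4r, p4c):
    """Interior-intersection indicator of segment (q, a) vs segment (p3, p4).

    All arguments broadcast; exact for integer inputs within the grid
    bound.
    """
    d1 = (p4r - p3r) * (qc - p3c) - (p4c - p3c) * (qr - p3r)
    d2 = (p4r - p3r) * (ac - p3c) - (p4c - p3c) * (ar - p3r)
    d3 = (ar - qr) * (p3c - qc) - (ac - qc) * (p3r - qr)
    d4 = (ar - qr) * (p4c - qc) - (ac - qc) * (p4r - qr)
    proper = _opp_sign(d1, d2) & _opp_sign(d3, d4)
    col = (d1 == 0) & (d2 == 0)
    if not col.any():
        return proper
    dr = p4r - p3r
    dc = p4c - p3c
    t4 = dr * dr + dc * dc
    tq = (qr - p3r) * dr + (qc - p3c) * dc
    ta = (ar - p3r) * dr + (ac - p3c) * dc
    lo = np.minimum(tq, ta)
    hi = np.maximum(tq, ta)
    overlap = np.maximum(lo, 0) < np.minimum(hi, t4)
    return proper | (col & overlap)


def _point_on_moving(qr, qc, ar, ac, zr, zc):
    """Indicator of point z strictly inside segment (q, a); broadcasts."""
    on_line = (ar - qr) * (zc - qc) - (ac - qc) * (zr - qr) == 0
    dot = (zr - qr) * (zr - ar) + (zc - qc) * (zc - ac)
    return on_line & (dot < 0)


def _moving_on_segment(qr, qc, p3r, p3c, p4r, p4c):
    """Indicator of moving point q strictly inside segment (p3, p4)."""
    on_line = (p4r - p3r) * (qc - p3c) - (p4c - p3c) * (qr - p3r) == 0
    dot = (qr - p3r) * (qr - p4r) + (qc - p3c) * (qc - p4c)
    return on_line & (dot < 0)


def cross_table(a: np.ndarray, segs: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum over segments ``segs`` (m,4) of I_e(seg(q, a), f) for every q."""
    qr, qc = _mesh(h, w)
    if segs.size == 0:
        return np.zeros((h, w), dtype=np.int64)
    s = segs.reshape(-1, 4).astype(np.int32)
    res = _cross_moving(
        qr, qc, np.int32(a[0]), np.int32(a[1]),
        s[:, 0, None, None], s[:, 1, None, None],
        s[:, 2, None, None], s[:, 3, None, None],
    )
    return res.sum(axis=0, dtype=np.int64)


def cross_table_each(a_arr: np.ndarray, seg: np.ndarray, h: int, w: int) -> np.ndarray:
    """(k, h, w) tables: I_e(seg(q, a_i), f) for a fixed segment f."""
    qr, qc = _mesh(h, w)
    a32 = a_arr.astype(np.int32)
    res = _cross_moving(
        qr, qc,
        a32[:, 0, None, None], a32[:, 1, None, None],
        np.int32(seg[0]), np.int32(seg[1]), np.int32(seg[2]), np.int32(seg[3]),
    )
    return res.astype(np.int64)


def points_on_moving_table(a: np.ndarray, zs: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum over points ``zs`` (m,2) of I_n(z, seg(q, a)) for every q."""
    qr, qc = _mesh(h, w)
    if zs.size == 0:
        return np.zeros((h, w), dtype=np.int64)
    z = zs.reshape(-1, 2).astype(np.int32)
    res = _point_on_moving(
        qr, qc, np.int32(a[0]), np.int32(a[1]),
        z[:, 0, None, None], z[:, 1, None, None],
    )
    return res.sum(axis=0, dtype=np.int64)


def point_on_moving_table_each(a_arr: np.ndarray, z: Sequence[int], h: int, w: int) -> np.ndarray:
    """(k, h, w) tables: I_n(z, seg(q, a_i)) for a fixed point z."""
    qr, qc = _mesh(h, w)
    a32 = a_arr.astype(np.int32)
    res = _point_on_moving(
        qr, qc,
        a32[:, 0, None, None], a32[:, 1, None, None],
        np.int32(z[0]), np.int32(z[1]),
    )
    return res.astype(np.int64)


def moving_on_segments_table(segs: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum over segments ``segs`` (m,4) of I_n(q, f) for every q."""
    qr, qc = _mesh(h, w)
    if segs.size == 0:
        return np.zeros((h, w), dtype=np.int64)
    s = segs.reshape(-1, 4).astype(np.int32)
    res = _moving_on_segment(
        qr, qc,
        s[:, 0, None, None], s[:, 1, None, None],
        s[:, 2, None, None], s[:, 3, None, None],
    )
    return res.sum(axis=0, dtype=np.int64)


def raw_candidate_tables(
    ui: int,
    pos: np.ndarray,
    edges: np.ndarray,
    neighbors: np.ndarray,
    grid: Grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-candidate crossing counts for node index ``ui``.

    ``EE[q]`` (``NE[q]``) is the number of edge-edge (node-edge)
    crossings *involving* ``ui`` if it sat at grid point ``q`` with all
    other nodes fixed.  At the node's current point the table equals
    its current contribution, so delta tables are raw minus that value.
    """
    h, w = grid.h, grid.w
    EE = np.zeros((h, w), dtype=np.int64)
    NE = np.zeros((h, w), dtype=np.int64)
    n = pos.shape[0]
    if edges.size:
        not_u = (edges[:, 0] != ui) & (edges[:, 1] != ui)
        segs = np.concatenate([pos[edges[not_u, 0]], pos[edges[not_u, 1]]], axis=1)
        NE += moving_on_segments_table(segs, h, w)
    for x in neighbors:
        a = pos[x]
        if edges.size:
            ok = (
                (edges[:, 0] != ui) & (edges[:, 1] != ui)
                & (edges[:, 0] != x) & (edges[:, 1] != x)
            )
            segs = np.concatenate([pos[edges[ok, 0]], pos[edges[ok, 1]]], axis=1)
            EE += cross_table(a, segs, h, w)
        zs = np.array([pos[z] for z in range(n) if z != ui and z != x], dtype=np.int64)
        NE += points_on_moving_table(a, zs, h, w)
    return EE, NE


@dataclass
class CandidateTable:
    """Per-grid-point (ee, ne) crossing deltas for moving one node."""

    node: str
    ee_delta: np.ndarray  # (h, w) int64
    ne_delta: np.ndarray  # (h, w) int64
    usable: np.ndarray    # (h, w) bool: vacant points (current point unusable)


def bulk_candidate_counts(
    v: str, graph: PathwayGraph, layout: Layout, grid: Grid
) -> CandidateTable:
    """Exact (ee, ne) change for moving node ``v`` to every grid point.

    Occupied points (including ``v``'s own) are flagged unusable; the
    delta at ``v``'s current point is (0, 0) by construction.
    """
    ids = sorted(graph.node_ids)
    index = {nid: i for i, nid in enumerate(ids)}
    pos = np.array([layout[nid] for nid in ids], dtype=np.int64)
    edges = np.array([[index[a], index[b]] for a, b in graph.edges],
                     dtype=np.int64).reshape(-1, 2)
    ui = index[v]
    nbrs = np.array(sorted(index[x] for x in graph.neighbors(v)), dtype=np.int64)
    EE, NE = raw_candidate_tables(ui, pos, edges, nbrs, grid)
    p = tuple(pos[ui])
    usable = np.ones((grid.h, grid.w), dtype=bool)
    for q in pos:
        usable[tuple(q)] = False
    return CandidateTable(v, EE - EE[p], NE - NE[p], usable)
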