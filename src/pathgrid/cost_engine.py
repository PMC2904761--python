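"""The layout cost function.

The total cost of a grid layout P is the weighted sum

    C(P) = w_a * sum_{(u,v) in E}  F_a(d(P(u), P(v)))      (attraction)
         + w_r * sum_{u < v}       F_r(d(P(u), P(v)))      (repulsion)
         + w_e * EE(P)                                     (edge-edge crossings)
         + w_n * NE(P)                                     (node-edge crossings)
         + alpha * exp(-beta * l) * S(P)                   (surface penalty)

with Euclidean distances in grid units, F_a(d) = d^2 and F_r(d) = 1/d^2
by default.  Attraction runs over each edge once and repulsion over
each unordered node pair once; multiplicative conventions are absorbed
by the weights, which keeps the default relation w_n = 2 * w_e
meaningful.  S(P) counts nodes within one grid unit of the surface of
a movable compartment and is active only in the dynamic-compartment
mode (``step`` is None otherwise), decaying to zero as the update step
counter l grows so the overall search still converges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import crossing_counter as cc
from .pathway_model import (
    CompartmentSpec,
    ConstraintMap,
    CostParams,
    Grid,
    Layout,
    LayoutError,
    PathwayGraph,
    validate_layout,
)


@dataclass
class CostBreakdown:
    """Component values of the layout cost; ``total`` is their weighted sum."""

    attraction: float
    repulsion: float
    ee_crossings: int
    ne_crossings: int
    surface_penalty: float
    total: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "attraction": self.attraction,
                "repulsion": self.repulsion,
                "ee_crossings": int(self.ee_crossings),
                "ne_crossings": int(self.ne_crossings),
                "surface_penalty": self.surface_penalty,
                "total": self.total,
            }
        )


def attraction_sum(graph: PathwayGraph, layout: Layout, F_a: Callable) -> float:
    """Sum of F_a(d) over edges, each edge once."""
    total = 0.0
    for a, b in graph.edges:
        pa, pb = layout[a], layout[b]
        total += float(F_a(math.hypot(pa[0] - pb[0], pa[1] - pb[1])))
    return total


def repulsion_sum(graph: PathwayGraph, layout: Layout, F_r: Callable) -> float:
    """Sum of F_r(d) over unordered node pairs, each pair once."""
    ids = graph.node_ids
    pos = np.array([layout[i] for i in ids], dtype=float)
    if len(ids) < 2:
        return 0.0
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(ids), k=1)
    return float(F_r(d[iu]).sum())


def surface_mask(
    compartments: Sequence[CompartmentSpec], grid: Grid
) -> np.ndarray:
    """Boolean (h, w) mask of grid points within one grid unit of a
    compartment surface.

    A surface cell is a region cell with a 4-neighbour outside the
    region (for an annulus this yields both the inner and the outer
    rim); the mask is that boundary dilated by its 4-neighbourhood,
    i.e. Euclidean distance <= 1 on the lattice.
    """
    h, w = grid.h, grid.w
    out = np.zeros((h, w), dtype=bool)
    for comp in compartments:
        m = comp.mask(grid)
        inside = np.pad(m, 1, constant_values=False)
        boundary = m & ~(
            inside[:-2, 1:-1] & inside[2:, 1:-1] & inside[1:-1, :-2] & inside[1:-1, 2:]
        )
        near = boundary.copy()
        near[1:, :] |= boundary[:-1, :]
        near[:-1, :] |= boundary[1:, :]
        near[:, 1:] |= boundary[:, :-1]
        near[:, :-1] |= boundary[:, 1:]
        out |= near
    return out


def surface_penalty(
    graph: PathwayGraph,
    layout: Layout,
    compartments: Sequence[CompartmentSpec],
    step: int | None,
    alpha: float,
    beta: float,
    grid: Grid,
) -> float:
    """alpha * exp(-beta * l) per node near a movable compartment surface.

    Returns 0 when the dynamic-compartment mode is off (``step`` is
    None).  Only movable compartments contribute: the penalty exists to
    keep nodes off surfaces that may still resize or move.
    """
    if step is None:
        return 0.0
    movable = [c for c in compartments if c.movable]
    if not movable:
        return 0.0
    mask = surface_mask(movable, grid)
    count = sum(1 for nid in graph.node_ids if mask[layout[nid]])
    return float(alpha) * math.exp(-beta * step) * count


def total_cost(
    graph: PathwayGraph,
    layout: Layout,
    params: CostParams,
    constraints: ConstraintMap,
    step: int | None = None,
) -> CostBreakdown:
    """Full cost breakdown of a valid, constraint-satisfying layout."""
    violations = validate_layout(graph, layout, constraints)
    if violations:
        raise LayoutError(
            "layout violates preconditions: "
            + "; ".join(v.message for v in violations[:5])
        )
    att = attraction_sum(graph, layout, params.F_a)
    rep = repulsion_sum(graph, layout, params.F_r)
    ee, ne = cc.count_all_crossings(graph, layout)
    pen = surface_penalty(
        graph, layout, constraints.compartments, step,
        params.resolved_alpha(constraints.grid), params.beta, constraints.grid,
    )
    total = (
        params.w_a * att + params.w_r * rep
        + params.w_e * ee + params.w_n * ne + pen
    )
    return CostBreakdown(att, rep, ee, ne, pen, total)
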