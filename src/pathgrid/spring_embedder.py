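"""Continuous-space force-directed baseline.

Classic spring embedder with attraction F_a(d) = d^2 along edges and
repulsion F_r(d) = 1/d^2 between all node pairs, iterated with
per-node displacement capped by a linearly cooling step size.  The
baseline ignores localization constraints entirely.

With these forces the equilibrium edge length is of order |V|^(1/4),
independent of the canvas, so for crossing comparisons against grid
layouts the final positions are rescaled to the grid bounding box and
snapped to vacant grid points by a minimum-squared-distance assignment
(:func:`snap_to_grid`).  Edge-edge crossing counts are invariant under
that positive anisotropic rescale; node-edge crossings only become
meaningful after snapping.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import crossing_counter as cc
from .pathway_model import Grid, Layout, PathwayGraph


class ContinuousLayout:
    """Real-valued node positions on a finite canvas."""

    def __init__(self, positions: dict[str, tuple[float, float]], canvas: tuple[float, float]):
        self.positions = {k: (float(v[0]), float(v[1])) for k, v in positions.items()}
        self.canvas = (float(canvas[0]), float(canvas[1]))

    def __getitem__(self, node_id: str) -> tuple[float, float]:
        return self.positions[node_id]

    def items(self):
        return self.positions.items()


def _forces(pos: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n = pos.shape[0]
    disp = np.zeros_like(pos)
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        # repulsion 1/d^2 directed away: (p_i - p_j) / d^3
        disp += (diff / (d ** 3)[..., None]).sum(axis=1)
    for a, b in edges:
        delta = pos[b] - pos[a]
        d = np.hypot(*delta)
        if d > 0:
            # attraction d^2 toward the neighbour: unit * d^2 = delta * d
            disp[a] += delta * d
            disp[b] -= delta * d
    return disp


def spring_step(
    pos: np.ndarray,
    edges: np.ndarray,
    step_size: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One capped-displacement update; coincident nodes are jittered."""
    pos = np.array(pos, dtype=float)
    n = pos.shape[0]
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        d2 = (diff ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if (d2 < 1e-18).any():
            jitter = (rng.normal(size=pos.shape) if rng is not None
                      else np.arange(2 * n, dtype=float).reshape(n, 2) + 1.0)
            pos = pos + 1e-6 * jitter
    disp = _forces(pos, edges)
    norm = np.sqrt((disp ** 2).sum(-1, keepdims=True))
    scale = np.minimum(1.0, step_size / np.maximum(norm, 1e-300))
    return pos + disp * scale


def spring_run(
    graph: PathwayGraph,
    canvas: tuple[float, float],
    iters: int = 500,
    seed: int = 0,
    step0: float | None = None,
) -> ContinuousLayout:
    """Run the embedder from a seeded random start; deterministic per seed."""
    if iters < 1:
        raise ValueError("iters must be >= 1")
    ids = sorted(graph.node_ids)
    index = {nid: i for i, nid in enumerate(ids)}
    edges = np.array([[index[a], index[b]] for a, b in graph.edges],
                     dtype=np.int64).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    hi = np.array([canvas[0] - 1.0, canvas[1] - 1.0], dtype=float)
    hi = np.maximum(hi, 1e-6)
    pos = rng.uniform(low=0.0, high=hi, size=(len(ids), 2))
    if step0 is None:
        step0 = 0.1 * float(min(canvas))
    for t in range(iters):
        s = step0 * (1.0 - t / iters)
        pos = spring_step(pos, edges, s, rng=rng)
        pos = np.clip(pos, 0.0, hi)
    return ContinuousLayout({nid: tuple(pos[i]) for i, nid in enumerate(ids)}, canvas)


def continuous_crossings(graph: PathwayGraph, layout: ContinuousLayout) -> tuple[int, int]:
    """(ee, ne) measured on the continuous segments (no snapping)."""
    return cc.count_crossings_of_positions(graph, layout.positions)


def snap_to_grid(layout: ContinuousLayout, grid: Grid) -> Layout:
    """Rescale to the grid bounding box and assign nearest vacant points.

    Axes rescale independently to fill the grid; the injective
    node-to-point assignment minimizes total squared displacement.
    """
    ids = sorted(layout.positions)
    pos = np.array([layout.positions[i] for i in ids], dtype=float)
    lo = pos.min(axis=0)
    span = pos.max(axis=0) - lo
    target = np.array([grid.h - 1.0, grid.w - 1.0])
    scaled = np.empty_like(pos)
    for ax in range(2):
        if span[ax] > 1e-12:
            scaled[:, ax] = (pos[:, ax] - lo[ax]) / span[ax] * target[ax]
        else:
            scaled[:, ax] = target[ax] / 2.0
    cells = np.array([(r, c) for r in range(grid.h) for c in range(grid.w)], dtype=float)
    cost = ((scaled[:, None, :] - cells[None, :, :]) ** 2).sum(-1)
    rows, cols = linear_sum_assignment(cost)
    out = {}
    for i, j in zip(rows, cols):
        out[ids[i]] = (int(cells[j][0]), int(cells[j][1]))
    return Layout(out)
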