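"""Dynamic resizing and repositioning of compartments (GDC mode).

Between passes of the greedy grid search, every movable compartment is
(i) resized according to how widely its localized nodes are spread and
(ii) repositioned so its center tracks the nodes' center of gravity:

* spread: s_v (s_h) is twice the maximum vertical (horizontal)
  deviation of the compartment's nodes from their centroid — a full
  extent proxy.  Shrink by 0.95 when s_v < 0.4*height AND
  s_h < 0.4*width; enlarge by 1/0.95 when s_v > 0.9*height OR
  s_h > 0.9*width; sizes are clamped to [0.6, 1.5] times the original.
* reposition: candidate centers are grid points within Manhattan
  distance 10 of the (discretized) centroid, taken in increasing
  Manhattan distance; a candidate is valid when every node still
  satisfies its localization, the compartment stays inside the grid
  (and its container, for nested scenes), and its bounding rectangle
  overlaps no sibling compartment.  If no candidate is valid the
  resize is reverted and the search repeated; failing that, size and
  position are kept for the next round.

A surface penalty alpha*exp(-beta*l) on nodes within one grid unit of
a movable compartment's surface keeps placements off surfaces early so
compartments stay free to change; it decays with the round counter l,
guaranteeing convergence.  The outer membrane / extracellular scene is
conventionally immovable.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cost_engine import CostBreakdown
from .grid_search import SearchState
from .pathway_model import (
    CompartmentSpec,
    ConstraintMap,
    CostParams,
    Grid,
    Layout,
    PathwayGraph,
    rect_inside_rect,
    rects_overlap_corner_test,
    rects_overlap_strict,
)

SHRINK_STEP = 0.95
SHRINK_THRESHOLD = 0.4
ENLARGE_THRESHOLD = 0.9
MIN_SCALE = 0.6
MAX_SCALE = 1.5
MAX_MANHATTAN = 10


@dataclass
class CompartmentState:
    """Per-round bookkeeping of one compartment's update."""

    spec: CompartmentSpec
    b_c: tuple[float, float] | None = None
    s_v: float = 0.0
    s_h: float = 0.0
    l: int = 0


def spread_statistics(points: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Centroid and full-extent spreads of a non-empty point cloud.

    ``s_v`` (``s_h``) is twice the maximum vertical (horizontal)
    distance from the centroid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("spread_statistics requires a non-empty node set")
    b = pts.mean(axis=0)
    s_v = 2.0 * float(np.abs(pts[:, 0] - b[0]).max())
    s_h = 2.0 * float(np.abs(pts[:, 1] - b[1]).max())
    return (float(b[0]), float(b[1])), s_v, s_h


def resize_decision(comp: CompartmentSpec, s_v: float, s_h: float) -> str:
    """'shrink' | 'enlarge' | 'keep' for the current spread statistics."""
    height, width = comp.size
    if s_v < SHRINK_THRESHOLD * height and s_h < SHRINK_THRESHOLD * width:
        new = (height * SHRINK_STEP, width * SHRINK_STEP)
        if (new[0] >= MIN_SCALE * comp.original_size[0] - 1e-12
                and new[1] >= MIN_SCALE * comp.original_size[1] - 1e-12):
            return "shrink"
        return "keep"
    if s_v > ENLARGE_THRESHOLD * height or s_h > ENLARGE_THRESHOLD * width:
        new = (height / SHRINK_STEP, width / SHRINK_STEP)
        if (new[0] <= MAX_SCALE * comp.original_size[0] + 1e-12
                and new[1] <= MAX_SCALE * comp.original_size[1] + 1e-12):
            return "enlarge"
        return "keep"
    return "keep"


def _ancestors(comp: CompartmentSpec, comps: Sequence[CompartmentSpec]) -> set[str]:
    by_id = {c.id: c for c in comps}
    out: set[str] = set()
    cur = comp
    while cur.container is not None and cur.container in by_id:
        out.add(cur.container)
        cur = by_id[cur.container]
    return out


def _related(a: CompartmentSpec, b: CompartmentSpec,
             comps: Sequence[CompartmentSpec]) -> bool:
    return b.id in _ancestors(a, comps) or a.id in _ancestors(b, comps)


def candidate_valid(
    candidate: CompartmentSpec,
    all_comps: Sequence[CompartmentSpec],
    graph: PathwayGraph,
    layout: Layout,
    grid: Grid,
    strict_overlap: bool = False,
) -> bool:
    """Both feasibility conditions for one resize/reposition candidate."""
    r0, r1, c0, c1 = candidate.bounding_rect()
    if r0 < -0.5 - 1e-9 or r1 > grid.h - 0.5 + 1e-9:
        return False
    if c0 < -0.5 - 1e-9 or c1 > grid.w - 0.5 + 1e-9:
        return False
    by_id = {c.id: c for c in all_comps}
    if candidate.container is not None and candidate.container in by_id:
        if not rect_inside_rect(candidate, by_id[candidate.container]):
            return False
    overlap = rects_overlap_strict if strict_overlap else rects_overlap_corner_test
    scene = [candidate if c.id == candidate.id else c for c in all_comps]
    for other in scene:
        if other.id == candidate.id or _related(candidate, other, scene):
            continue
        if overlap(candidate, other):
            return False
    # every node localized to a tag served by this compartment must
    # remain inside the (updated) union region of its tag
    affected_tags = set(candidate.tags)
    for node in graph.nodes:
        if node.localization not in affected_tags:
            continue
        p = layout[node.id]
        ok = any(
            c.contains(p) for c in scene if node.localization in c.tags
        )
        if not ok:
            return False
    return True


def reposition(
    comp: CompartmentSpec,
    b_c: tuple[float, float],
    all_comps: Sequence[CompartmentSpec],
    graph: PathwayGraph,
    layout: Layout,
    grid: Grid,
    max_manhattan: int = MAX_MANHATTAN,
    strict_overlap: bool = False,
) -> tuple[float, float] | None:
    """Closest valid center to the node centroid, or None.

    Candidate centers are grid points within Manhattan distance
    ``max_manhattan`` of the discretized centroid, scanned in
    increasing (Manhattan distance, row, col) order; the first valid
    candidate is therefore the minimizer.
    """
    br = int(math.floor(b_c[0] + 0.5))
    bc = int(math.floor(b_c[1] + 0.5))
    cands: list[tuple[int, int, int]] = []
    for dr in range(-max_manhattan, max_manhattan + 1):
        rem = max_manhattan - abs(dr)
        for dcol in range(-rem, rem + 1):
            r, c = br + dr, bc + dcol
            if 0 <= r < grid.h and 0 <= c < grid.w:
                cands.append((abs(dr) + abs(dcol), r, c))
    cands.sort()
    for _, r, c in cands:
        cand = comp.with_center((r, c))
        if candidate_valid(cand, all_comps, graph, layout, grid,
                           strict_overlap=strict_overlap):
            return (float(r), float(c))
    return None


@dataclass
class RoundEntry:
    round: int
    comp_id: str
    decision: str
    size: tuple[float, float]
    center: tuple[float, float]
    changed: bool


def update_compartments_round(
    comps: list[CompartmentSpec],
    graph: PathwayGraph,
    layout: Layout,
    grid: Grid,
    round_no: int,
    strict_overlap: bool = False,
) -> tuple[bool, list[RoundEntry]]:
    """One resize+reposition round over all movable compartments.

    Mutates ``comps`` in place (replacing updated specs); returns
    whether anything changed plus the per-compartment trace entries.
    """
    changed_any = False
    entries: list[RoundEntry] = []
    order = sorted(
        (i for i, c in enumerate(comps) if c.movable), key=lambda i: comps[i].id
    )
    for i in order:
        comp = comps[i]
        node_pts = np.array(
            [layout[n.id] for n in graph.nodes if n.localization in comp.tags],
            dtype=float,
        ).reshape(-1, 2)
        if node_pts.shape[0] == 0:
            entries.append(RoundEntry(round_no, comp.id, "skip-empty",
                                      comp.size, comp.center, False))
            continue
        b_c, s_v, s_h = spread_statistics(node_pts)
        decision = resize_decision(comp, s_v, s_h)
        factor = {"shrink": SHRINK_STEP, "enlarge": 1.0 / SHRINK_STEP, "keep": 1.0}[decision]
        trial = comp.scaled(factor) if factor != 1.0 else comp
        center = reposition(trial, b_c, comps, graph, layout, grid,
                            strict_overlap=strict_overlap)
        applied = decision
        if center is None and factor != 1.0:
            # revert the size change, retry repositioning only
            trial = comp
            applied = "keep"
            center = reposition(trial, b_c, comps, graph, layout, grid,
                                strict_overlap=strict_overlap)
        if center is None:
            # keep current size and position for the next step
            entries.append(RoundEntry(round_no, comp.id, "stuck",
                                      comp.size, comp.center, False))
            continue
        updated = trial.with_center(center)
        changed = (updated.size != comp.size) or (updated.center != comp.center)
        comps[i] = updated
        changed_any |= changed
        entries.append(RoundEntry(round_no, comp.id, applied,
                                  updated.size, updated.center, changed))
    return changed_any, entries


def _next_enable_round(state: SearchState, pen_floor: float) -> int | None:
    """Smallest l at which penalty decay re-enables some move.

    During a no-op round nothing changes except l, so the first move to
    become profitable is the candidate whose penalty-free delta is most
    negative among moves stepping onto the surface band.  Returns None
    if no such move exists before the penalty reaches ``pen_floor``.
    """
    best = 0.0
    for ui in range(state.n):
        allowed = state.admissible_vacant(ui)
        if not allowed.any():
            continue
        base = state.delta_table(ui, include_penalty=False)
        p = tuple(state.pos[ui])
        ds = state.surface - state.surface[p]
        cand = allowed & (ds > 0) & (base < -state.tol)
        if cand.any():
            best = max(best, float(-(base[cand]).min()))
    need = best - state.tol
    if need <= pen_floor:
        return None
    # alpha * exp(-beta*l) < need  =>  l > ln(alpha/need)/beta
    l = int(math.floor(math.log(state.alpha / need) / state.beta)) + 1
    return max(l, state.l + 1)


def gdc_optimize(
    graph: PathwayGraph,
    grid: Grid,
    constraints: ConstraintMap,
    params: CostParams,
    initial_layout: Layout | None = None,
    seed: int | None = None,
    max_steps: int | None = None,
    max_rounds: int = 5000,
    pen_decay_tol: float = 1e-3,
    strict_overlap: bool = False,
) -> tuple[Layout, list[CompartmentSpec], dict]:
    """Grid layout with dynamic compartment update.

    Interleaves one grid-search pass (up to |V| accepted moves) with
    one compartment resize/reposition round, incrementing the penalty
    step counter l per round.  No-op rounds are fast-forwarded
    analytically (see module docstring); after the main loop the
    penalty is annealed below ``pen_decay_tol * alpha`` and a short
    polish pass makes the result a local optimum of the undecayed cost.
    With every compartment immovable this reduces exactly to the plain
    grid search.
    """
    if initial_layout is None:
        from .synthetic_pathways import random_layout

        initial_layout = random_layout(graph, grid, constraints,
                                       seed=0 if seed is None else seed)
    if max_steps is None:
        max_steps = 10 * max(1, graph.n_nodes)
    comps = [copy.deepcopy(c) for c in constraints.compartments]
    tags = sorted(state_tags for state_tags in {n.localization for n in graph.nodes})
    cm = ConstraintMap.from_compartments(comps, grid, tags) if comps else constraints
    state = SearchState(graph, grid, cm, params, initial_layout, gdc=True)
    l_floor = int(math.ceil(math.log(1.0 / pen_decay_tol) / params.beta))
    comp_trace: list[RoundEntry] = []
    rounds = 0
    while rounds < max_rounds and state.steps < max_steps:
        moved = state.run(max_moves=min(state.n, max_steps - state.steps))
        changed, entries = update_compartments_round(
            comps, graph, state.layout(), grid, rounds,
            strict_overlap=strict_overlap,
        )
        comp_trace.extend(entries)
        if changed:
            cm = ConstraintMap.from_compartments(comps, grid, tags)
            state.refresh_constraints(cm)
            state.refresh_surface()
        state.l += 1
        rounds += 1
        if moved == 0 and not changed:
            nxt = _next_enable_round(state, pen_decay_tol * state.alpha)
            if nxt is None or nxt >= l_floor:
                break
            state.l = nxt
    # anneal the penalty out and polish to a local optimum of the
    # undecayed cost
    state.l = max(state.l, l_floor)
    state.run(max_moves=2 * state.n)
    final_layout = state.layout()
    trace = {
        "cost": state.trace,
        "compartments": comp_trace,
        "rounds": rounds,
        "steps": state.steps,
        "final_penalty_scale": state.penalty_scale(),
    }
    return final_layout, comps, trace
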