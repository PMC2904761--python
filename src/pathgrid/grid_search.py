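"""Greedy grid-layout optimizer with incremental delta-cost caches.

At each step the optimizer moves the single node whose relocation to an
admissible vacant grid point decreases the total cost the most, until
no move helps.  The naive cost of one step is O(|V|^2 * h * w); the
caches below bring it down to roughly the cost of refreshing the few
tables a move actually touches:

* ``RepulsionField`` stores sum_u F_r(d(q, P(u))) for every grid point
  q; the repulsion delta of any candidate move is then O(1) reads, and
  a move updates the field with two kernel additions.
* Per-node *raw candidate tables* store, for every grid point q, the
  attraction sum and the crossing counts node u would contribute if it
  sat at q.  The delta of u -> q is the raw value at q minus the raw
  value at u's current point.  Moving node v rebuilds the tables of
  v's neighbours only and adjusts every other node's crossing tables
  by the crossings gained/lost against v's relocated edges and point —
  the standard case analysis of edge-edge and node-edge interactions
  between the moved node and the rest of the graph.

Cache-vs-scratch equality after every move is the engineering claim
the test suite checks on small random instances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import crossing_counter as cc
from .cost_engine import CostBreakdown, surface_mask, total_cost
from .pathway_model import (
    ConstraintMap,
    CostParams,
    Grid,
    GridPoint,
    Layout,
    LayoutError,
    PathwayGraph,
    validate_layout,
)


def _group_add(dest: np.ndarray, idx_sorted: np.ndarray, T: np.ndarray) -> None:
    """dest[i] += sum of T rows whose (sorted) index is i."""
    uniq, starts = np.unique(idx_sorted, return_index=True)
    sums = np.add.reduceat(T, starts, axis=0)
    dest[uniq] += sums


@dataclass(frozen=True)
class Move:
    node: str
    point: GridPoint
    delta: float


def _kernel(func, grid: Grid) -> np.ndarray:
    """(2h-1, 2w-1) table of func(distance) over all integer offsets.

    The zero-offset entry is set to 0 so a node never interacts with
    its own position (the self-term of the repulsion field).
    """
    h, w = grid.h, grid.w
    dr = np.arange(-(h - 1), h, dtype=float)[:, None]
    dc = np.arange(-(w - 1), w, dtype=float)[None, :]
    d = np.sqrt(dr * dr + dc * dc)
    k = np.asarray(func(d), dtype=float)
    k[h - 1, w - 1] = 0.0
    return k


class SearchState:
    """Layout, occupancy, and all delta-cost caches of one search run.

    Exposes the repulsion field (``field``) and per-node raw candidate
    tables (``A`` attraction, ``EE``/``NE`` crossings); delta tables
    are derived on demand in :meth:`delta_table`.
    """

    def __init__(
        self,
        graph: PathwayGraph,
        grid: Grid,
        constraints: ConstraintMap,
        params: CostParams,
        layout: Layout,
        gdc: bool = False,
        tol: float = 1e-9,
        refresh_every: int = 200,
    ):
        violations = validate_layout(graph, layout, constraints)
        if violations:
            raise LayoutError(
                "initial layout inadmissible: "
                + "; ".join(v.message for v in violations[:10])
            )
        self.graph = graph
        self.grid = grid
        self.constraints = constraints
        self.params = params
        self.gdc = gdc
        self.tol = tol
        self.refresh_every = refresh_every

        self.ids = sorted(graph.node_ids)
        self.index = {nid: i for i, nid in enumerate(self.ids)}
        n = len(self.ids)
        h, w = grid.h, grid.w
        self.n = n
        self.edges = np.array(
            [[self.index[a], self.index[b]] for a, b in graph.edges], dtype=np.int64
        ).reshape(-1, 2)
        self.adj = [
            np.array(sorted(self.index[x] for x in graph.neighbors(nid)), dtype=np.int64)
            for nid in self.ids
        ]
        # directed edge list (tail, head), sorted by tail so incremental
        # updates can aggregate per-tail contributions with reduceat
        if self.edges.size:
            tail = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            head = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            order = np.argsort(tail, kind="stable")
            self._dir_tail = tail[order]
            self._dir_head = head[order]
        else:
            self._dir_tail = np.zeros(0, dtype=np.int64)
            self._dir_head = np.zeros(0, dtype=np.int64)

        self.pos = np.array([layout[nid] for nid in self.ids], dtype=np.int64)
        self.occ = np.full((h, w), -1, dtype=np.int64)
        for i in range(n):
            self.occ[tuple(self.pos[i])] = i

        self.Fa_k = _kernel(params.F_a, grid)
        self.Fr_k = _kernel(params.F_r, grid)
        self.tags = [graph.localization(nid) for nid in self.ids]
        self._tag_masks = {t: constraints.mask_for(t) for t in set(self.tags)}

        self.alpha = params.resolved_alpha(grid)
        self.beta = params.beta
        self.l = 0
        self.steps = 0
        self.trace: list[CostBreakdown] = []

        self.field = np.zeros((h, w), dtype=float)
        self.A = np.zeros((n, h, w), dtype=float)
        self.EE = np.zeros((n, h, w), dtype=np.int64)
        self.NE = np.zeros((n, h, w), dtype=np.int64)
        self._rebuild_all_tables()
        self.refresh_surface()
        self._init_sums()
        self._warn_frozen()

    # -- cache construction ------------------------------------------
    def _slice(self, kernel: np.ndarray, p) -> np.ndarray:
        h, w = self.grid.h, self.grid.w
        r, c = int(p[0]), int(p[1])
        return kernel[h - 1 - r : 2 * h - 1 - r, w - 1 - c : 2 * w - 1 - c]

    def _rebuild_attraction(self, ui: int) -> None:
        h, w = self.grid.h, self.grid.w
        acc = np.zeros((h, w), dtype=float)
        for x in self.adj[ui]:
            acc += self._slice(self.Fa_k, self.pos[x])
        self.A[ui] = acc

    def _rebuild_crossings(self, ui: int) -> None:
        self.EE[ui], self.NE[ui] = cc.raw_candidate_tables(
            ui, self.pos, self.edges, self.adj[ui], self.grid
        )

    def _rebuild_all_tables(self) -> None:
        self.field = np.zeros((self.grid.h, self.grid.w), dtype=float)
        for i in range(self.n):
            self.field += self._slice(self.Fr_k, self.pos[i])
        for i in range(self.n):
            self._rebuild_attraction(i)
            self._rebuild_crossings(i)

    def refresh_constraints(self, constraints: ConstraintMap) -> None:
        """Re-bind admissibility masks after compartment geometry changed."""
        self.constraints = constraints
        self._tag_masks = {t: constraints.mask_for(t) for t in set(self.tags)}

    def refresh_surface(self) -> None:
        movable = [c for c in self.constraints.compartments if c.movable]
        if self.gdc and movable:
            self.surface = surface_mask(movable, self.grid).astype(np.int64)
        else:
            self.surface = np.zeros((self.grid.h, self.grid.w), dtype=np.int64)

    def _init_sums(self) -> None:
        layout = self.layout()
        from .cost_engine import attraction_sum, repulsion_sum

        self.sum_a = attraction_sum(self.graph, layout, self.params.F_a)
        self.sum_r = repulsion_sum(self.graph, layout, self.params.F_r)
        self.ee, self.ne = cc.count_all_crossings(self.graph, layout)

    def _warn_frozen(self) -> None:
        vac = self.occ < 0
        for i, nid in enumerate(self.ids):
            if not (self._tag_masks[self.tags[i]] & vac).any():
                warnings.warn(
                    f"node {nid!r} has no admissible vacant grid point; "
                    "frozen this pass", stacklevel=2,
                )

    # -- queries ------------------------------------------------------
    def layout(self) -> Layout:
        return Layout({nid: tuple(self.pos[i]) for i, nid in enumerate(self.ids)})

    def penalty_scale(self) -> float:
        if not self.gdc:
            return 0.0
        return self.alpha * math.exp(-self.beta * self.l)

    def surface_count(self) -> int:
        return int(sum(self.surface[tuple(self.pos[i])] for i in range(self.n)))

    def breakdown(self) -> CostBreakdown:
        pen = self.penalty_scale() * self.surface_count()
        p = self.params
        total = (
            p.w_a * self.sum_a + p.w_r * self.sum_r
            + p.w_e * self.ee + p.w_n * self.ne + pen
        )
        return CostBreakdown(self.sum_a, self.sum_r, self.ee, self.ne, pen, total)

    def delta_table(self, ui: int, include_penalty: bool = True) -> np.ndarray:
        """Total-cost change for moving node ``ui`` to every grid point."""
        p = tuple(self.pos[ui])
        prm = self.params
        D = prm.w_a * (self.A[ui] - self.A[ui][p])
        D += prm.w_r * (self.field - self._slice(self.Fr_k, p) - self.field[p])
        D += prm.w_e * (self.EE[ui] - self.EE[ui][p])
        D += prm.w_n * (self.NE[ui] - self.NE[ui][p])
        if include_penalty:
            pen = self.penalty_scale()
            if pen:
                D = D + pen * (self.surface - self.surface[p])
        return D

    def admissible_vacant(self, ui: int) -> np.ndarray:
        return self._tag_masks[self.tags[ui]] & (self.occ < 0)

    # -- the greedy step ----------------------------------------------
    def best_move(self) -> Move | None:
        """Most cost-decreasing admissible (node, vacant point) move.

        Ties break to the lexicographically lowest (node id, row, col);
        node ids are scanned in ascending order.  Returns None at
        convergence (no move with delta < -tol).
        """
        w = self.grid.w
        best_d = np.inf
        best = None
        for ui in range(self.n):
            allowed = self.admissible_vacant(ui)
            if not allowed.any():
                continue
            D = np.where(allowed, self.delta_table(ui), np.inf)
            k = int(D.argmin())
            d = D.flat[k]
            if d < best_d:
                best_d = d
                best = (ui, divmod(k, w))
        if best is None or best_d >= -self.tol:
            return None
        ui, point = best
        return Move(self.ids[ui], point, float(best_d))

    def apply_move(self, move: Move) -> CostBreakdown:
        """Apply an admissible move and incrementally update all caches."""
        vi = self.index[move.node]
        q = (int(move.point[0]), int(move.point[1]))
        p = tuple(self.pos[vi])
        if self.occ[q] != -1:
            raise LayoutError(f"target {q} occupied: delta-cost cache corrupted")
        # component deltas read off the caches before mutation
        d_a = self.A[vi][q] - self.A[vi][p]
        d_r = self.field[q] - self._slice(self.Fr_k, p)[q] - self.field[p]
        d_ee = int(self.EE[vi][q] - self.EE[vi][p])
        d_ne = int(self.NE[vi][q] - self.NE[vi][p])

        self.occ[p] = -1
        self.occ[q] = vi
        self.pos[vi] = q

        self.field -= self._slice(self.Fr_k, p)
        self.field += self._slice(self.Fr_k, q)

        self._adjust_crossing_tables(vi, p, q)
        for x in self.adj[vi]:
            self._rebuild_attraction(int(x))
            self._rebuild_crossings(int(x))

        self.sum_a += d_a
        self.sum_r += d_r
        self.ee += d_ee
        self.ne += d_ne
        self.steps += 1
        if self.refresh_every and self.steps % self.refresh_every == 0:
            # cure float accumulation drift in field and running sums
            self._rebuild_all_tables()
            self._init_sums()
        bd = self.breakdown()
        self.trace.append(bd)
        return bd

    def _adjust_crossing_tables(self, vi: int, p_old, p_new) -> None:
        """Cases (i)-(v): patch crossing tables of nodes outside N(v).

        v's own tables never reference v's position and stay exact; the
        tables of v's neighbours are rebuilt by the caller.
        """
        h, w = self.grid.h, self.grid.w
        nbrs = self.adj[vi]
        stale = np.zeros(self.n, dtype=bool)
        stale[vi] = True
        stale[nbrs] = True
        ns = np.nonzero(~stale)[0]
        if ns.size == 0:
            return
        # u (any non-stale node) as a moving point on v's relocated edges
        if nbrs.size:
            old_segs = np.concatenate(
                [np.tile(p_old, (len(nbrs), 1)), self.pos[nbrs]], axis=1
            )
            new_segs = np.concatenate(
                [np.tile(p_new, (len(nbrs), 1)), self.pos[nbrs]], axis=1
            )
            self.NE[ns] -= cc.moving_on_segments_table(old_segs, h, w)
            self.NE[ns] += cc.moving_on_segments_table(new_segs, h, w)
        # directed edges (u, x) whose tail u is non-stale
        if self._dir_tail.size:
            sel = ~stale[self._dir_tail]
            if sel.any():
                tails = self._dir_tail[sel]  # still sorted ascending
                heads = self._dir_head[sel]
                a = self.pos[heads]
                # v as a point on candidate segments (q, P(x))
                T = cc.point_on_moving_table_each(a, p_new, h, w)
                T -= cc.point_on_moving_table_each(a, p_old, h, w)
                _group_add(self.NE, tails, T)
                # candidate segments vs v's relocated edges
                for y in nbrs:
                    py = self.pos[int(y)]
                    m = heads != y  # skip shared graph endpoint x == y
                    if not m.any():
                        continue
                    f_old = np.array([p_old[0], p_old[1], py[0], py[1]], dtype=np.int64)
                    f_new = np.array([p_new[0], p_new[1], py[0], py[1]], dtype=np.int64)
                    T = cc.cross_table_each(a[m], f_new, h, w)
                    T -= cc.cross_table_each(a[m], f_old, h, w)
                    _group_add(self.EE, tails[m], T)

    def run(self, max_moves: int | None = None) -> int:
        """Accept best moves until convergence or ``max_moves``; returns count."""
        done = 0
        while max_moves is None or done < max_moves:
            mv = self.best_move()
            if mv is None:
                break
            self.apply_move(mv)
            done += 1
        return done


def init_caches(
    graph: PathwayGraph,
    layout: Layout,
    params: CostParams,
    constraints: ConstraintMap,
    gdc: bool = False,
) -> SearchState:
    """Build the repulsion field and all per-node delta-cost tables."""
    return SearchState(graph, constraints.grid, constraints, params, layout, gdc=gdc)


def best_move(state: SearchState) -> Move | None:
    return state.best_move()


def apply_move_and_update(state: SearchState, move: Move) -> SearchState:
    state.apply_move(move)
    return state


def optimize(
    graph: PathwayGraph,
    grid: Grid,
    constraints: ConstraintMap,
    params: CostParams,
    initial_layout: Layout | None = None,
    max_steps: int | None = None,
    seed: int | None = None,
    log_path=None,
) -> tuple[Layout, list[CostBreakdown]]:
    """Greedy descent to a locally optimal admissible layout.

    ``seed`` only draws the initial random layout when none is given;
    the search itself is deterministic.  The returned trace holds one
    cost breakdown per accepted move, with totals strictly decreasing.
    """
    if initial_layout is None:
        from .synthetic_pathways import random_layout

        initial_layout = random_layout(graph, grid, constraints,
                                       seed=0 if seed is None else seed)
    if max_steps is None:
        max_steps = 10 * max(1, graph.n_nodes)
    state = SearchState(graph, grid, constraints, params, initial_layout)
    state.run(max_moves=max_steps)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for i, bd in enumerate(state.trace):
                fh.write(f'{{"step": {i + 1}, "cost": {bd.to_json()}}}\n')
    return state.layout(), state.trace
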