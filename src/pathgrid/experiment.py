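"""Replicated layout comparisons across modes.

Reproduces the study protocol: a set of random initial layouts of one
pathway is given to each requested mode and the resulting cost and
crossing counts are tabulated, with box-plot style quartile summaries.

Modes: ``grid`` (constrained greedy grid layout), ``grid-nl`` (the
same with positional constraints disabled), ``gdc`` (grid layout with
dynamic compartment update), ``spring`` (the continuous baseline; its
crossings are counted after snapping to the grid, its cost is the grid
cost of the snapped layout).
"""

from __future__ import annotations

import time

import pandas as pd

from . import crossing_counter as cc
from .compartment_dynamics import gdc_optimize
from .cost_engine import total_cost
from .grid_search import optimize
from .pathway_model import (
    ConfigurationError,
    ConstraintMap,
    CostParams,
    Grid,
    PathwayGraph,
)
from .spring_embedder import snap_to_grid, spring_run
from .synthetic_pathways import generate_pathway, grid_for_nodes, random_layout

MODES = ("grid", "grid-nl", "gdc", "spring")
METRICS = ("total_cost", "ee", "ne", "steps")


def run_experiment(config: dict) -> pd.DataFrame:
    """One row per (mode, replicate): mode, seed, total cost, ee, ne, steps."""
    modes = config.get("modes", ["grid"])
    for m in modes:
        if m not in MODES:
            raise ConfigurationError(f"unknown mode {m!r}; choose from {MODES}")
    replicates = int(config.get("replicates", 10))
    base_seed = int(config.get("seed", 0))
    n_nodes = int(config.get("nodes", 53))
    n_edges = int(config.get("edges", 59))
    preset = config.get("preset")
    if preset:
        from .pathway_model import PRESETS

        params = PRESETS[preset]()
    else:
        params = CostParams(
            w_a=float(config.get("w_a", 1.0)),
            w_r=float(config.get("w_r", 1.0)),
            w_e=float(config.get("w_e", 10.0)),
            w_n=float(config["w_n"]) if "w_n" in config else None,
        )
    max_steps = config.get("max_steps")

    graph, comps = generate_pathway(n_nodes, n_edges, seed=base_seed)
    if "grid" in config and config["grid"]:
        h, w = (int(x) for x in str(config["grid"]).lower().split("x"))
        grid = Grid(h, w)
    else:
        grid = grid_for_nodes(n_nodes)
    tags = sorted({n.localization for n in graph.nodes})
    cm = ConstraintMap.from_compartments(comps, grid, tags)
    cm_nl = ConstraintMap.unconstrained(grid, tags)

    rows = []
    for mode in modes:
        for i in range(replicates):
            seed_i = base_seed + i
            t0 = time.perf_counter()
            if mode == "spring":
                cont = spring_run(graph, (grid.h, grid.w), seed=seed_i)
                layout = snap_to_grid(cont, grid)
                ee, ne = cc.count_all_crossings(graph, layout)
                bd = total_cost(graph, layout, params, cm_nl)
                steps = 0
            elif mode == "gdc":
                layout0 = random_layout(graph, grid, cm, seed=seed_i)
                layout, final_comps, trace = gdc_optimize(
                    graph, grid, cm, params, layout0, max_steps=max_steps
                )
                ee, ne = cc.count_all_crossings(graph, layout)
                cm_final = ConstraintMap.from_compartments(final_comps, grid, tags)
                bd = total_cost(graph, layout, params, cm_final)
                steps = trace["steps"]
            else:
                this_cm = cm if mode == "grid" else cm_nl
                layout0 = random_layout(graph, grid, this_cm, seed=seed_i)
                layout, trace = optimize(
                    graph, grid, this_cm, params, layout0, max_steps=max_steps
                )
                ee, ne = cc.count_all_crossings(graph, layout)
                bd = total_cost(graph, layout, params, this_cm)
                steps = len(trace)
            rows.append(
                {
                    "mode": mode,
                    "seed": seed_i,
                    "total_cost": bd.total,
                    "ee": ee,
                    "ne": ne,
                    "steps": steps,
                    "runtime_s": time.perf_counter() - t0,
                }
            )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics (min, quartiles, max) per mode and metric."""
    return (
        df.groupby("mode")[list(METRICS)]
        .quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        .rename_axis(["mode", "quantile"])
    )
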