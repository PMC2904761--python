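"""Readers, writers and SVG rendering.

Graphs travel as GraphML (nodes carry ``localization`` and ``label``
data keys) or as a minimal JSON dialect::

    {"nodes": [{"id": ..., "label": ..., "localization": ...}, ...],
     "edges": [["a", "b"], ...]}

Compartment scenes and layouts are plain JSON.  The SVG renderer draws
compartments (rectangle / oval / annulus frame), straight edges and
node glyphs — a stand-in for heavyweight pathway-editor formats.
"""

from __future__ import annotations

import json
from typing import Sequence
from xml.sax.saxutils import escape

import networkx as nx

from .pathway_model import (
    CompartmentSpec,
    GraphError,
    Grid,
    Layout,
    PathwayGraph,
    PathwayNode,
)


class ParseError(ValueError):
    """Malformed input file, with element context where available."""


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def read_json(path) -> PathwayGraph:
    with open(path) as fh:
        data = json.load(fh)
    try:
        nodes = [
            PathwayNode(
                id=str(n["id"]),
                label=str(n.get("label", n["id"])),
                localization=str(n["localization"]),
            )
            for n in data["nodes"]
        ]
        edges = [tuple(map(str, e)) for e in data["edges"]]
    except KeyError as exc:
        raise ParseError(f"{path}: missing required field {exc}") from exc
    try:
        return PathwayGraph(nodes, edges)
    except GraphError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_json(graph: PathwayGraph, path) -> None:
    data = {
        "nodes": [
            {"id": n.id, "label": n.label, "localization": n.localization}
            for n in graph.nodes
        ],
        "edges": [list(e) for e in graph.edges],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_graphml(path) -> PathwayGraph:
    g = nx.read_graphml(path)
    nodes = []
    for nid, attrs in g.nodes(data=True):
        if "localization" not in attrs:
            raise ParseError(f"{path}: node {nid!r} lacks a 'localization' data key")
        nodes.append(
            PathwayNode(
                id=str(nid),
                label=str(attrs.get("label", nid)),
                localization=str(attrs["localization"]),
            )
        )
    edges = [(str(a), str(b)) for a, b in g.edges()]
    try:
        return PathwayGraph(nodes, edges)
    except GraphError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_graphml(graph: PathwayGraph, path) -> None:
    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(n.id, label=n.label, localization=n.localization)
    g.add_edges_from(graph.edges)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------

def read_compartments_json(path) -> list[CompartmentSpec]:
    with open(path) as fh:
        data = json.load(fh)
    comps = []
    for entry in data:
        try:
            comps.append(
                CompartmentSpec(
                    id=str(entry["id"]),
                    shape=str(entry["shape"]),
                    center=tuple(entry["center"]),
                    size=tuple(entry["size"]),
                    inner_size=tuple(entry["inner_size"]) if "inner_size" in entry else None,
                    movable=bool(entry.get("movable", False)),
                    tags=tuple(entry.get("tags", ())),
                    container=entry.get("container"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: bad compartment entry {entry.get('id', '?')!r}: {exc}") from exc
    return comps


def write_compartments_json(comps: Sequence[CompartmentSpec], path) -> None:
    data = []
    for c in comps:
        entry = {
            "id": c.id, "shape": c.shape,
            "center": list(c.center), "size": list(c.size),
            "movable": c.movable, "tags": list(c.tags),
        }
        if c.inner_size is not None:
            entry["inner_size"] = list(c.inner_size)
        if c.container is not None:
            entry["container"] = c.container
        data.append(entry)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

def write_layout_json(layout: Layout, grid: Grid, path, mode: str = "grid") -> None:
    data = {
        "grid": {"h": grid.h, "w": grid.w},
        "mode": mode,
        "positions": {nid: list(p) for nid, p in sorted(layout.items())},
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_layout_json(path) -> tuple[Layout, Grid]:
    with open(path) as fh:
        data = json.load(fh)
    grid = Grid(int(data["grid"]["h"]), int(data["grid"]["w"]))
    layout = Layout({nid: tuple(p) for nid, p in data["positions"].items()})
    return layout, grid


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

_TAG_COLORS = {
    "extracellular": "#dddddd",
    "plasma_membrane": "#4477cc",
    "cytoplasm": "#f4f0e0",
    "nuclear_membrane": "#886600",
    "nucleus": "#e8d44d",
    "mitochondria": "#cc4444",
    "golgi": "#996633",
}


def render_svg(
    path,
    graph: PathwayGraph,
    layout: Layout,
    compartments: Sequence[CompartmentSpec] = (),
    grid: Grid | None = None,
    scale: int = 24,
    labels: bool = False,
) -> None:
    """Write an SVG drawing: compartments below, edges, then node glyphs."""
    if grid is None:
        h = 1 + max((p[0] for _, p in layout.items()), default=0)
        w = 1 + max((p[1] for _, p in layout.items()), default=0)
        grid = Grid(max(1, h), max(1, w))
    s = scale
    pad = s

    def xy(p):
        # grid (row, col) -> svg (x, y)
        return pad + p[1] * s, pad + p[0] * s

    width = grid.w * s + 2 * pad
    height = grid.h * s + 2 * pad
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="white"/>',
    ]

    def rect_svg(center, size, stroke, fill="none"):
        x, y = xy((center[0] - size[0] / 2.0, center[1] - size[1] / 2.0))
        return (
            f'<rect class="compartment" x="{x:.1f}" y="{y:.1f}" '
            f'width="{size[1] * s:.1f}" height="{size[0] * s:.1f}" '
            f'fill="{fill}" stroke="{stroke}" stroke-width="2"/>'
        )

    for comp in compartments:
        color = _TAG_COLORS.get(comp.tags[0] if comp.tags else "", "#888888")
        if comp.shape == "rectangle":
            parts.append(rect_svg(comp.center, comp.size, color))
        elif comp.shape == "oval":
            x, y = xy(comp.center)
            parts.append(
                f'<ellipse class="compartment" cx="{x:.1f}" cy="{y:.1f}" '
                f'rx="{comp.size[1] / 2 * s:.1f}" ry="{comp.size[0] / 2 * s:.1f}" '
                f'fill="none" stroke="{color}" stroke-width="2"/>'
            )
        else:  # annulus frame: outer and inner outlines
            parts.append(rect_svg(comp.center, comp.size, color))
            parts.append(rect_svg(comp.center, comp.inner_size, color))

    for a, b in graph.edges:
        xa, ya = xy(layout[a])
        xb, yb = xy(layout[b])
        parts.append(
            f'<line class="edge" x1="{xa:.1f}" y1="{ya:.1f}" x2="{xb:.1f}" y2="{yb:.1f}" '
            f'stroke="#333333" stroke-width="1.5"/>'
        )

    for node in graph.nodes:
        x, y = xy(layout[node.id])
        color = _TAG_COLORS.get(node.localization, "#66aa66")
        parts.append(
            f'<circle class="node" cx="{x:.1f}" cy="{y:.1f}" r="{s * 0.28:.1f}" '
            f'fill="{color}" stroke="#222222" stroke-width="1"/>'
        )
        if labels:
            parts.append(
                f'<text x="{x:.1f}" y="{y - s * 0.35:.1f}" font-size="{s * 0.4:.0f}" '
                f'text-anchor="middle">{escape(node.label)}</text>'
            )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
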