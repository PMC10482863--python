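"""Waterfall layouts (age on the vertical axis) and graph file exports.

The waterfall drawing arranges nodes top-down by time of origin: the y
coordinate is the node's age rank (older at the top), while the x
coordinate spreads nodes horizontally with a stress-minimizing
(Kamada-Kawai) pass run only within each community, communities tiled left
to right.  Symbol sizes follow weighted degrees shifted by 10 so that
0-degree entities do not vanish: for directed nets the horizontal size
tracks the weighted outdegree and the vertical size the weighted indegree.

Exports: Pajek .net/.clu (1-based vertices; node age is stored as the z
coordinate so a round trip recovers it), GraphML, and TSV edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

DEGREE_SHIFT = 10.0


@dataclass
class NodeGlyph:
    x: float
    y: float
    width: float
    height: float
    color_key: float  # age


@dataclass
class ArcGlyph:
    source: str
    target: str
    width: float
    color_key: float  # destination age


@dataclass
class WaterfallLayout:
    nodes: dict[str, NodeGlyph]
    arcs: list[ArcGlyph]


def waterfall_layout(
    net: nx.Graph | nx.DiGraph,
    partition: dict | None = None,
    seed: int = 0,
    size_scale: float = 1.0,
) -> WaterfallLayout:
    """Deterministic waterfall coordinates for an aged, partitioned network."""
    ages = nx.get_node_attributes(net, "age")
    if len(ages) != net.number_of_nodes():
        raise ValueError("waterfall_layout: every node needs an age")
    if partition is None:
        partition = {n: 0 for n in net.nodes}
    missing = set(net.nodes) - set(partition)
    if missing:
        raise ValueError(f"waterfall_layout: {len(missing)} nodes missing from partition")

    # y: dense age rank, older at top (smaller y)
    events = sorted(set(ages.values()))
    rank = {a: i for i, a in enumerate(events)}

    if net.is_directed():
        w_out = dict(net.out_degree(weight="weight"))
        w_in = dict(net.in_degree(weight="weight"))
    else:
        w_out = w_in = dict(net.degree(weight="weight"))

    # x: per community Kamada-Kawai on the community subgraph, tiled left to right
    rng = np.random.default_rng(seed)
    comms: dict = {}
    for n, c in partition.items():
        if n in net:
            comms.setdefault(c, []).append(n)
    xcoord: dict[str, float] = {}
    offset = 0.0
    gap = 1.0
    for c in sorted(comms, key=str):
        members = sorted(comms[c])
        sub = net.subgraph(members).to_undirected()
        if len(members) == 1:
            pos = {members[0]: (0.0, 0.0)}
        else:
            init = {
                n: (np.cos(2 * np.pi * i / len(members)), np.sin(2 * np.pi * i / len(members)))
                for i, n in enumerate(members)
            }
            pos = nx.kamada_kawai_layout(sub, pos=init)
        xs = np.array([pos[n][0] for n in members])
        xs = xs - xs.min()
        span = xs.max() if xs.max() > 0 else 1.0
        for n, xv in zip(members, xs):
            xcoord[n] = offset + float(xv)
        offset += span + gap
    _ = rng  # reserved for future jitter of exactly overlapping nodes

    glyphs = {
        n: NodeGlyph(
            x=xcoord[n],
            y=float(rank[ages[n]]),
            width=(w_out[n] + DEGREE_SHIFT) * size_scale,
            height=(w_in[n] + DEGREE_SHIFT) * size_scale,
            color_key=ages[n],
        )
        for n in net.nodes
    }
    arcs = [
        ArcGlyph(
            source=u,
            target=v,
            width=float(d.get("weight", 1)),
            color_key=ages[v],
        )
        for u, v, d in net.edges(data=True)
    ]
    return WaterfallLayout(nodes=glyphs, arcs=arcs)


# --------------------------------------------------------------------------
# exports

def export_graph(
    net: nx.Graph | nx.DiGraph,
    path: str | Path,
    fmt: str = "pajek",
    layout: WaterfallLayout | None = None,
) -> list[Path]:
    """Write a network to disk; returns the list of files written.

    ``pajek`` writes ``<path>.net`` (vertices with x y coordinates and age as
    z, arcs/edges with weights) plus ``<path>.clu`` (age-event partition,
    1-based classes).  ``graphml`` writes a single file with all attributes.
    ``edgelist`` writes a TSV with source, target, weight.
    """
    path = Path(path)
    if fmt == "pajek":
        return _write_pajek(net, path, layout)
    if fmt == "graphml":
        out = path.with_suffix(".graphml")
        nx.write_graphml(net, out)
        return [out]
    if fmt == "edgelist":
        out = path.with_suffix(".tsv")
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            out, sep="\t", index=False
        )
        return [out]
    raise ValueError(f"unknown format {fmt!r}")


def _write_pajek(net, path: Path, layout: WaterfallLayout | None) -> list[Path]:
    nodes = sorted(net.nodes)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    ages = nx.get_node_attributes(net, "age")
    events = sorted(set(ages.values()))
    event_class = {a: i + 1 for i, a in enumerate(events)}
    net_path = path.with_suffix(".net")
    clu_path = path.with_suffix(".clu")
    with open(net_path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            if layout is not None and n in layout.nodes:
                g = layout.nodes[n]
                x, y = g.x, g.y
            else:
                x = y = 0.0
            fh.write(f'{index[n]} "{n}" {x:.6f} {y:.6f} {ages.get(n, 0.0):.6f}\n')
        fh.write("*Arcs\n" if net.is_directed() else "*Edges\n")
        for u, v, d in net.edges(data=True):
            fh.write(f"{index[u]} {index[v]} {d.get('weight', 1)}\n")
    with open(clu_path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f"{event_class.get(ages.get(n), 1)}\n")
    return [net_path, clu_path]


def read_pajek(path: str | Path) -> nx.Graph | nx.DiGraph:
    """Read back a ``.net`` file written by :func:`export_graph`.

    Node ages are recovered from the z coordinate; weights from the arc
    lines.  Directedness follows the ``*Arcs``/``*Edges`` section header.
    """
    path = Path(path)
    nodes: dict[int, tuple[str, float]] = {}
    edges: list[tuple[int, int, float]] = []
    directed = False
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                continue
            if low.startswith("*arcs"):
                section, directed = "edges", True
                continue
            if low.startswith("*edges"):
                section = "edges"
                continue
            if section == "vertices":
                idx_str, rest = line.split(" ", 1)
                label = rest.split('"')[1]
                coords = rest.rsplit('"', 1)[1].split()
                age = float(coords[2]) if len(coords) >= 3 else 0.0
                nodes[int(idx_str)] = (label, age)
            elif section == "edges":
                parts = line.split()
                w = float(parts[2]) if len(parts) > 2 else 1.0
                edges.append((int(parts[0]), int(parts[1]), w))
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    for idx, (label, age) in nodes.items():
        g.add_node(label, age=age)
    for u, v, w in edges:
        w = int(w) if float(w).is_integer() else w
        g.add_edge(nodes[u][0], nodes[v][0], weight=w)
    return g
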