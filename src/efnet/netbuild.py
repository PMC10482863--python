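"""Construction of the EF bipartite network, projections, and event series.

The EF (elementary functionome) network is the undirected, unweighted
bipartite graph linking modular loop prototypes to the domains that contain
them.  Each side projects to a one-mode directed network: two loops are
linked when they co-occur in a domain (and vice versa), the arc points from
the older to the younger node (seeded coin flip for contemporaneous pairs),
and the arc weight counts the shared partners.

Graphs are networkx objects; every node carries ``age`` (nd) and ``kind``
(``"loop"`` or ``"domain"``) attributes, and node keys are the serialized
identifier strings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from efnet.age_classify import PrototypeClassification
from efnet.io_formats import Chronology, MappingTable, PrototypeId

logger = logging.getLogger(__name__)


@dataclass
class EventNetworkSeries:
    """Cumulative snapshots of a growing network, one per distinct node age."""

    events: list[float]
    snapshots: list[nx.Graph]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(zip(self.events, self.snapshots))

    @property
    def final(self) -> nx.Graph:
        return self.snapshots[-1]


def build_bipartite(
    mapping: MappingTable,
    chronology: Chronology,
    loop_ages: dict[PrototypeId, float],
    subset: str = "all",
    classification: PrototypeClassification | None = None,
) -> nx.Graph:
    """Build the bipartite loop-domain graph, optionally restricted by label.

    ``subset`` is ``"all"``, ``"M"`` (the EF network proper; also includes
    ``"M'"`` when requested as ``"M+M'"``) or ``"NM"`` (the one-to-one
    "ripple" network).  Restricting requires a ``classification``.
    """
    keep: set[PrototypeId] | None = None
    if subset != "all":
        if classification is None:
            raise ValueError("subset filtering requires a classification")
        if subset == "M+M'":
            keep = classification.loops_with_label("M") | classification.loops_with_label("M'")
        else:
            keep = classification.loops_with_label(subset)
    g = nx.Graph()
    for rec in mapping.records:
        if keep is not None and rec.loop not in keep:
            continue
        lnode, dnode = str(rec.loop), str(rec.domain)
        if lnode not in g:
            if rec.loop not in loop_ages:
                raise ValueError(f"build_bipartite: no age for loop {lnode}")
            g.add_node(lnode, kind="loop", age=loop_ages[rec.loop], bipartite=0)
        if dnode not in g:
            g.add_node(dnode, kind="domain", age=chronology.ages[rec.domain], bipartite=1)
        g.add_edge(lnode, dnode)
    if g.number_of_nodes() == 0:
        warnings.warn(f"build_bipartite: subset {subset!r} produced an empty network")
    return g


def project(bip: nx.Graph, side: str = "loop", seed: int = 0) -> nx.DiGraph:
    """One-mode directed weighted projection of a bipartite network.

    Exactly one arc per connected unordered pair, pointing old -> young;
    contemporaneous pairs are oriented by a seeded coin flip.  Arc weight is
    the number of shared bipartite partners.
    """
    if side not in ("loop", "domain"):
        raise ValueError("side must be 'loop' or 'domain'")
    rng = np.random.default_rng(seed)
    nodes = [n for n, d in bip.nodes(data=True) if d["kind"] == side]
    proj = nx.DiGraph()
    for n in nodes:
        proj.add_node(n, kind=side, age=bip.nodes[n]["age"])
    neighbors = {n: set(bip.neighbors(n)) for n in nodes}
    for u, v in combinations(sorted(nodes), 2):
        shared = len(neighbors[u] & neighbors[v])
        if shared == 0:
            continue
        au, av = bip.nodes[u]["age"], bip.nodes[v]["age"]
        if au < av:
            src, dst = u, v
        elif av < au:
            src, dst = v, u
        else:
            src, dst = (u, v) if rng.random() < 0.5 else (v, u)
        proj.add_edge(src, dst, weight=shared)
    return proj


def event_series(net: nx.Graph | nx.DiGraph) -> EventNetworkSeries:
    """Cumulative induced subgraphs at every distinct node age of ``net``."""
    ages = nx.get_node_attributes(net, "age")
    if len(ages) != net.number_of_nodes():
        raise ValueError("event_series: every node needs an 'age' attribute")
    events = sorted(set(ages.values()))
    snapshots = []
    for t in events:
        keep = [n for n, a in ages.items() if a <= t]
        snapshots.append(net.subgraph(keep).copy())
    return EventNetworkSeries(events=events, snapshots=snapshots)


def combined_weighted_degree(net: nx.DiGraph) -> dict[str, float]:
    """Weighted indegree + outdegree per node (plain degree for undirected)."""
    if net.is_directed():
        din = dict(net.in_degree(weight="weight"))
        dout = dict(net.out_degree(weight="weight"))
        return {n: din[n] + dout[n] for n in net.nodes}
    return dict(net.degree(weight="weight"))


def hub_subnetwork(net: nx.DiGraph, percentile: float = 99.0) -> nx.DiGraph:
    """Subnetwork of hub nodes above a combined weighted-degree percentile.

    Keeps nodes whose combined (in + out) weighted degree is strictly above
    the given percentile of all nodes; arcs between surviving contemporaneous
    nodes are dropped.  ``percentile <= 0`` keeps every node.
    """
    if percentile >= 100:
        raise ValueError("percentile must be < 100")
    degs = combined_weighted_degree(net)
    if percentile <= 0:
        keep = set(degs)
    else:
        cut = float(np.percentile(list(degs.values()), percentile))
        keep = {n for n, d in degs.items() if d > cut}
    sub = net.subgraph(keep).copy()
    drop = [
        (u, v)
        for u, v in sub.edges
        if sub.nodes[u]["age"] == sub.nodes[v]["age"]
    ]
    sub.remove_edges_from(drop)
    if sub.number_of_nodes() == 0:
        warnings.warn("hub_subnetwork: empty result")
    return sub


# -- density / average-degree identities -------------------------------------
#
# These are the closed-form network descriptors used for whole-network
# summaries: density of a bipartite graph is links over the product of the
# two node-set sizes, density of a directed one-mode graph is arcs over
# n(n-1), and average degree is links-per-node.

def bipartite_density(n_loops: int, n_domains: int, n_edges: int) -> float:
    """Bipartite density: actual / possible links = E / (n_loops * n_domains)."""
    if n_loops <= 0 or n_domains <= 0:
        raise ValueError("node counts must be positive")
    return n_edges / (n_loops * n_domains)


def projection_density(n_nodes: int, n_arcs: int) -> float:
    """Directed one-mode density: arcs / (n * (n - 1))."""
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return n_arcs / (n_nodes * (n_nodes - 1))


def average_degree(n_nodes: int, n_edges: int, directed: bool = False) -> float:
    """Node average degree: links per node (2E/n undirected, E/n per direction)."""
    if n_nodes <= 0:
        raise ValueError("need >= 1 node")
    return (1 if directed else 2) * n_edges / n_nodes


def graph_density(net: nx.Graph | nx.DiGraph) -> float:
    """Density of a built graph, dispatching on bipartite vs one-mode."""
    kinds = {d["kind"] for _, d in net.nodes(data=True)}
    if kinds == {"loop", "domain"}:
        n_l = sum(1 for _, d in net.nodes(data=True) if d["kind"] == "loop")
        return bipartite_density(n_l, net.number_of_nodes() - n_l, net.number_of_edges())
    if net.is_directed():
        return projection_density(net.number_of_nodes(), net.number_of_edges())
    return nx.density(net)
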