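import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from efnet.io_formats import (
    Chronology,
    MappingRecord,
    MappingTable,
    parse_prototype_id,
    parse_scop_ccs,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def mk_mapping(pairs, evalues=None):
    """MappingTable from [(loop_str, domain_str), ...]."""
    records = []
    for i, (l, d) in enumerate(pairs):
        ev = evalues[i] if evalues else None
        records.append(MappingRecord(parse_prototype_id(l), parse_scop_ccs(d), ev))
    return MappingTable(records=records)


def mk_chron(ages):
    """Chronology from {domain_str: nd}."""
    return Chronology(ages={parse_scop_ccs(d): nd for d, nd in ages.items()})


def ng_oracle(g: nx.Graph, partition: dict) -> float:
    """Brute-force Newman-Girvan Q: (1/2m) sum_ij (A_ij - k_i k_j/2m) delta."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    m2 = k.sum()
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


@pytest.fixture
def toy_bipartite():
    """3 loops x 3 domains with spread ages; used across netbuild tests."""
    from efnet.age_classify import assign_loop_ages, loop_age_map
    from efnet.netbuild import build_bipartite

    mapping = mk_mapping(
        [
            ("DS.HE.3.1.1", "c.2.1.2"),
            ("DS.HE.3.1.1", "c.37.1.12"),
            ("DS.EH.0.1.17", "c.37.1.12"),
            ("DS.EH.0.1.17", "b.40.4.5"),
            ("DS.GG.2.1.1", "b.40.4.5"),
        ]
    )
    chron = mk_chron({"c.2.1.2": 0.0, "c.37.1.12": 0.1, "b.40.4.5": 0.5})
    ages = loop_age_map(assign_loop_ages(mapping, chron))
    return build_bipartite(mapping, chron, ages, subset="all")


def random_aged_bipartite(seed: int, n_loops=8, n_domains=6, p=0.4) -> nx.Graph:
    """Random small bipartite loop-domain graph with random ages."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    loop_ages = rng.choice([0.0, 0.2, 0.5, 0.8], size=n_loops)
    dom_ages = rng.choice([0.0, 0.2, 0.5, 0.8], size=n_domains)
    for i in range(n_loops):
        g.add_node(f"L{i}", kind="loop", age=float(loop_ages[i]))
    for j in range(n_domains):
        g.add_node(f"D{j}", kind="domain", age=float(dom_ages[j]))
    for i in range(n_loops):
        for j in range(n_domains):
            if rng.random() < p:
                g.add_edge(f"L{i}", f"D{j}")
    return g
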