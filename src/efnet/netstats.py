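"""Per-event network statistics: degrees, power-law fits, modularity indices.

Scale-free behaviour is assessed two ways, as is conventional for degree
distributions:

* a log-log linear regression of the empirical degree distribution P(k) on
  k, yielding the power-law slope magnitude gamma and the determination
  coefficient R^2;
* a discrete maximum-likelihood fit of P(X = x) ∝ x^(-alpha) for x >= xmin
  (zeta normalization), with a Kolmogorov-Smirnov goodness-of-fit statistic
  and a semi-parametric bootstrap p-value (null: the data are power-law).

Modularity is quantified with six indices per event: the VOS quality VQ,
the average clustering coefficient C, the clustering ratio C-ratio
(communities per connected node), the fast-greedy community modularity FGC,
and Newman-Girvan modularity under the age partition (NG_age) and under the
detected community partition (NG_vos).  Pairwise modularity matrices
(A_ij - k_i k_j / 2m, scaled by |log10| of NG_age) feed Ward dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.cluster.hierarchy import linkage, to_tree

from efnet.netbuild import EventNetworkSeries, combined_weighted_degree


class DegenerateDistributionError(ValueError):
    """Degree vector carries no distributional information (all values equal)."""


# --------------------------------------------------------------------------
# degrees

def degree_vectors(
    series: EventNetworkSeries, mode: str = "all", weighted: bool = True
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Cumulative per-event degree tables and the average-degree curve.

    Returns one DataFrame per event with columns ``node``, ``indegree``,
    ``outdegree``, ``alldegree`` (in/out are zero for undirected nets), and a
    summary frame with per-event mean, max and mean/max-normalized average
    degree.  ``mode`` selects which column feeds the summary ("all", "in",
    "out").
    """
    if mode not in ("all", "in", "out"):
        raise ValueError("mode must be 'all', 'in' or 'out'")
    w = "weight" if weighted else None
    frames = []
    rows = []
    for event, g in series:
        if g.is_directed():
            din = dict(g.in_degree(weight=w))
            dout = dict(g.out_degree(weight=w))
        else:
            din = {n: 0 for n in g.nodes}
            dout = dict(din)
        dall = dict(g.degree(weight=w))
        nodes = sorted(g.nodes)
        df = pd.DataFrame(
            {
                "node": nodes,
                "indegree": [din[n] for n in nodes],
                "outdegree": [dout[n] for n in nodes],
                "alldegree": [
                    din[n] + dout[n] if g.is_directed() else dall[n] for n in nodes
                ],
            }
        )
        frames.append(df)
        col = {"all": "alldegree", "in": "indegree", "out": "outdegree"}[mode]
        vec = df[col].to_numpy(dtype=float)
        mx = vec.max() if len(vec) else np.nan
        mean = vec.mean() if len(vec) else np.nan
        rows.append(
            {
                "event": event,
                "n_nodes": len(vec),
                "mean_degree": mean,
                "max_degree": mx,
                "norm_mean_degree": mean / mx if mx and mx > 0 else np.nan,
            }
        )
    return frames, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# discrete power law

def _zeta(alpha: float, xmin: int) -> float:
    return float(special.zeta(alpha, xmin))


def _loglik(alpha: float, n: int, sum_log: float, xmin: int) -> float:
    return -n * np.log(_zeta(alpha, xmin)) - alpha * sum_log


def _mle_alpha(x: np.ndarray, xmin: int) -> tuple[float, float]:
    n = len(x)
    sum_log = float(np.sum(np.log(x)))
    res = optimize.minimize_scalar(
        lambda a: -_loglik(a, n, sum_log, xmin),
        bounds=(1.001, 12.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


def _fitted_cdf(ks: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    z = _zeta(alpha, xmin)
    return 1.0 - special.zeta(alpha, np.asarray(ks, dtype=float) + 1.0) / z


def _ks_stat(x: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.sort(x)
    uniq, counts = np.unique(xs, return_counts=True)
    ecdf = np.cumsum(counts) / len(xs)
    model = _fitted_cdf(uniq, alpha, xmin)
    ecdf_lo = np.concatenate([[0.0], ecdf[:-1]])
    return float(np.max(np.maximum(np.abs(ecdf - model), np.abs(ecdf_lo - model))))


_CDF_CACHE: dict[tuple[float, int], tuple[np.ndarray, float]] = {}


def _cdf_table(alpha: float, xmin: int) -> tuple[np.ndarray, float]:
    """CDF over the head of the support (tail mass < 1e-6) and the normalizer."""
    key = (alpha, xmin)
    if key not in _CDF_CACHE:
        z = _zeta(alpha, xmin)
        hi = xmin + 1024
        while special.zeta(alpha, hi) / z > 1e-6 and hi < 10_000_000:
            hi *= 2
        ks = np.arange(xmin, hi, dtype=float)
        cdf = np.cumsum(ks ** (-alpha)) / z
        if len(_CDF_CACHE) > 32:
            _CDF_CACHE.clear()
        _CDF_CACHE[key] = (cdf, z)
    return _CDF_CACHE[key]


def _tail_quantile(u: float, alpha: float, xmin: int, z: float, lo: int) -> int:
    """Smallest x with CDF(x) >= u, for u beyond the tabulated head (bisection)."""
    hi = lo * 2
    while 1.0 - special.zeta(alpha, hi + 1) / z < u:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if 1.0 - special.zeta(alpha, mid + 1) / z < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


def sample_discrete_power_law(
    alpha: float, n: int, xmin: int = 1, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Exact inverse-CDF sampling of the discrete power law P(x) ∝ x^-alpha, x >= xmin."""
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cdf, z = _cdf_table(alpha, xmin)
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    out = (idx + xmin).astype(np.int64)
    tail = np.nonzero(idx >= len(cdf))[0]  # rare draws beyond the tabulated head
    for i in tail:
        out[i] = _tail_quantile(float(u[i]), alpha, xmin, z, len(cdf) + xmin)
    return out


@dataclass
class PowerLawFit:
    gamma: float
    r_squared: float
    alpha: float
    ks_stat: float
    ks_p: float
    loglik: float
    xmin: int
    n: int


def fit_power_law(
    degrees,
    bootstrap_reps: int = 100,
    seed: int | None = None,
    xmin: int | None = None,
) -> PowerLawFit:
    """Fit a discrete power law to a degree vector.

    gamma and R^2 come from the log-log regression of the empirical P(k);
    alpha from the zeta-normalized discrete MLE; the KS statistic compares
    the empirical CDF with the fitted one over x >= xmin; ks_p is the
    fraction of ``bootstrap_reps`` synthetic samples (drawn from the fitted
    model, refitted each time) whose KS statistic is at least as large as
    the observed one.  ``xmin`` defaults to the smallest positive degree —
    whole-distribution fits.
    """
    x = np.asarray(degrees, dtype=float)
    x = x[x > 0]
    if len(x) < 10:
        raise ValueError("fit_power_law: need >= 10 nonzero degrees")
    if np.all(x == x[0]):
        raise DegenerateDistributionError("all degrees equal; no distribution to fit")
    x = np.round(x).astype(np.int64)
    if xmin is None:
        xmin = int(x.min())
    x_fit = x[x >= xmin]
    rng = np.random.default_rng(seed)

    # log-log regression of the empirical distribution
    uniq, counts = np.unique(x, return_counts=True)
    pk = counts / counts.sum()
    lx, ly = np.log10(uniq.astype(float)), np.log10(pk)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0

    alpha, ll = _mle_alpha(x_fit, xmin)
    ks = _ks_stat(x_fit, alpha, xmin)

    ks_p = np.nan
    if bootstrap_reps > 0:
        n_boot = len(x_fit)
        exceed = 0
        for _ in range(bootstrap_reps):
            xb = sample_discrete_power_law(alpha, n_boot, xmin=xmin, rng=rng)
            ab, _ = _mle_alpha(xb, xmin)
            if _ks_stat(xb, ab, xmin) >= ks:
                exceed += 1
        ks_p = exceed / bootstrap_reps

    return PowerLawFit(
        gamma=abs(float(slope)),
        r_squared=max(0.0, min(1.0, r2)),
        alpha=alpha,
        ks_stat=ks,
        ks_p=ks_p,
        loglik=ll,
        xmin=xmin,
        n=len(x_fit),
    )


# --------------------------------------------------------------------------
# reference growth models

def generate_reference_network(
    n: int, kind: str = "barabasi", edges_per_node: int = 1, seed: int | None = None
) -> nx.DiGraph:
    """Grow a preferential-attachment reference network with recorded ages.

    ``barabasi``: each new node attaches ``edges_per_node`` arcs to distinct
    existing nodes with probability proportional to their current degree.
    ``barabasi_age``: probability proportional to degree times the linear
    age bonus (t - birth + 1) / t, favouring older nodes.  Node age is the
    birth rank normalized to [0, 1]; arcs point old -> new (weight 1).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if edges_per_node < 1:
        raise ValueError("edges_per_node must be >= 1")
    if kind not in ("barabasi", "barabasi_age"):
        raise ValueError("kind must be 'barabasi' or 'barabasi_age'")
    rng = np.random.default_rng(seed)
    deg = np.zeros(n, dtype=float)
    birth = np.arange(n, dtype=float)
    g = nx.DiGraph()
    g.add_node(0, age=0.0, kind="reference")
    for t in range(1, n):
        g.add_node(t, age=t / (n - 1), kind="reference")
        m = min(edges_per_node, t)
        w = deg[:t].copy()
        if kind == "barabasi_age":
            w = w * ((t - birth[:t] + 1.0) / t)
        if w.sum() <= 0:
            w = np.ones(t)
        targets = rng.choice(t, size=m, replace=False, p=w / w.sum())
        for tgt in targets:
            g.add_edge(int(tgt), t, weight=1)
            deg[tgt] += 1
            deg[t] += 1
    return g


# --------------------------------------------------------------------------
# modularity

def _simplified(net: nx.Graph | nx.DiGraph, weighted: bool = True) -> nx.Graph:
    """Undirected view; parallel opposite arcs merge by summing weights."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        w = d.get("weight", 1) if weighted else 1
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def _is_bipartite_loop_domain(net) -> bool:
    kinds = {d.get("kind") for _, d in net.nodes(data=True)}
    return kinds == {"loop", "domain"}


def ng_modularity(net: nx.Graph | nx.DiGraph, partition: dict) -> float:
    """Newman-Girvan modularity Q of a node partition.

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) on the weighted
    undirected simplification of ``net``.  The trivial single-community
    partition gives 0; values lie in [-1, 1].
    """
    g = _simplified(net)
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"ng_modularity: {len(missing)} nodes missing from partition")
    m = g.size(weight="weight")
    if m == 0:
        raise ValueError("ng_modularity: graph has no edges")
    deg = dict(g.degree(weight="weight"))
    comm_deg: dict = {}
    comm_in: dict = {}
    for node, c in partition.items():
        if node in deg:
            comm_deg[c] = comm_deg.get(c, 0.0) + deg[node]
    for u, v, d in g.edges(data=True):
        if partition[u] == partition[v]:
            w = d["weight"] * (1 if u == v else 2)  # A_ij counted both orders
            comm_in[partition[u]] = comm_in.get(partition[u], 0.0) + w
    q = 0.0
    for c, kc in comm_deg.items():
        q += comm_in.get(c, 0.0) / (2 * m) - (kc / (2 * m)) ** 2
    return float(q)


def age_partition(net) -> dict:
    """Partition nodes by their time event (distinct nd value)."""
    return {n: d["age"] for n, d in net.nodes(data=True)}


def detect_communities(
    net: nx.Graph | nx.DiGraph, method: str = "greedy", seed: int | None = None
) -> tuple[dict, float]:
    """Community detection on the weighted undirected simplification.

    ``greedy`` is the fast-greedy agglomerative modularity maximizer;
    ``vos_like`` is a seeded modularity-maximizing clustering (Louvain)
    standing in for the VOS layout clustering.  Returns (partition dict,
    Newman-Girvan quality of that partition).
    """
    g = _simplified(net)
    if g.number_of_edges() == 0:
        raise ValueError("detect_communities: graph has no edges")
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
    elif method == "vos_like":
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    else:
        raise ValueError("method must be 'greedy' or 'vos_like'")
    partition = {n: i for i, c in enumerate(comms) for n in c}
    return partition, ng_modularity(g, partition)


def clustering_stats(series: EventNetworkSeries) -> pd.DataFrame:
    """Per-event average clustering coefficient C and clustering ratio.

    C is the mean triangle/triad ratio over all nodes of the simplified
    (undirected, unweighted) snapshot; nodes of degree < 2 contribute 0.
    Bipartite snapshots have no triangles by construction and C is reported
    as NaN.  C-ratio is detected communities per non-isolated node.  The
    returned frame also carries, as attrs, the log-log regression exponents
    of C against network size N and against the event age nd (zeros and
    undefined values excluded).
    """
    rows = []
    for event, g in series:
        gs = _simplified(g, weighted=False)
        n = gs.number_of_nodes()
        if _is_bipartite_loop_domain(gs) or n == 0:
            c = np.nan
        else:
            c = nx.average_clustering(gs, count_zeros=True) if n else np.nan
        connected = sum(1 for _, d in gs.degree() if d > 0)
        if gs.number_of_edges() > 0:
            part, _ = detect_communities(gs, method="greedy")
            c_ratio = len(set(part.values())) / connected if connected else np.nan
        else:
            c_ratio = np.nan
        rows.append({"event": event, "n_nodes": n, "c": c, "c_ratio": c_ratio})
    df = pd.DataFrame(rows)
    df.attrs["c_vs_n_exponent"] = _loglog_exponent(df["n_nodes"], df["c"])
    df.attrs["c_vs_nd_exponent"] = _loglog_exponent(df["event"], df["c"])
    return df


def _loglog_exponent(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(np.log10(x[ok]), np.log10(y[ok]), 1)
    return float(slope)


@dataclass
class ModularityReport:
    """The six per-event modularity indices."""

    vq: float
    c: float
    c_ratio: float
    fgc: float
    ng_age: float
    ng_vos: float
    n_communities: int


def modularity_report(net, seed: int | None = None) -> ModularityReport:
    """Compute all six modularity indices for one network snapshot."""
    gs = _simplified(net, weighted=False)
    if _is_bipartite_loop_domain(net):
        c = np.nan
    else:
        c = nx.average_clustering(gs, count_zeros=True) if gs.number_of_nodes() else np.nan
    vos_part, vq = detect_communities(net, method="vos_like", seed=seed)
    _, fgc = detect_communities(net, method="greedy")
    n_comm = len(set(vos_part.values()))
    connected = sum(1 for _, d in gs.degree() if d > 0)
    return ModularityReport(
        vq=vq,
        c=float(c) if c == c else np.nan,
        c_ratio=n_comm / connected if connected else np.nan,
        fgc=fgc,
        ng_age=ng_modularity(net, age_partition(net)),
        ng_vos=ng_modularity(net, vos_part),
        n_communities=n_comm,
    )


@dataclass
class PairwiseModularityMatrix:
    """Scaled modularity matrix B_ij = (A_ij - k_i k_j / 2m) * M_nd."""

    nodes: list
    entries: np.ndarray
    m: float
    m_nd: float
    event: float

    def block(self, row_kind: str, col_kind: str, kinds: dict) -> np.ndarray:
        ri = [i for i, n in enumerate(self.nodes) if kinds[n] == row_kind]
        ci = [i for i, n in enumerate(self.nodes) if kinds[n] == col_kind]
        return self.entries[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.nodes, columns=self.nodes)


def pairwise_modularity_matrix(
    bip: nx.Graph,
    event: float | None = None,
    m_nd: float | None = None,
) -> PairwiseModularityMatrix:
    """Scaled pairwise modularity matrix of a (snapshot of a) network.

    If ``event`` is given, the cumulative snapshot of nodes with age <=
    event is used.  The unscaled matrix always sums to zero; the scale
    M_nd defaults to |log10(|NG_age|)| of the snapshot, falling back to 1
    (with a warning) when NG_age is 0 or undefined.
    """
    g = bip
    if event is not None:
        keep = [n for n, d in bip.nodes(data=True) if d["age"] <= event]
        g = bip.subgraph(keep)
    g = _simplified(g)
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("pairwise_modularity_matrix: empty snapshot")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    k = a.sum(axis=1)
    m = k.sum() / 2.0
    b = a - np.outer(k, k) / (2.0 * m)
    if m_nd is None:
        ng = ng_modularity(g, age_partition(g))
        if ng == 0:
            warnings.warn("NG_age is 0; modularity-matrix scaling undefined, using M_nd = 1")
            m_nd = 1.0
        else:
            m_nd = abs(np.log10(abs(ng)))
    ev = event if event is not None else max(d["age"] for _, d in g.nodes(data=True))
    return PairwiseModularityMatrix(nodes=nodes, entries=b * m_nd, m=m, m_nd=float(m_nd), event=ev)


def ward_dendrogram(matrix) -> tuple[np.ndarray, list]:
    """Ward's minimum-variance hierarchical clustering of the matrix rows.

    Accepts a PairwiseModularityMatrix or a 2-D array; returns the scipy
    linkage matrix (merge heights non-decreasing) and the row labels.
    Dissimilarities are squared Euclidean distances between cluster means,
    as Ward's criterion prescribes.
    """
    if isinstance(matrix, PairwiseModularityMatrix):
        rows, labels = matrix.entries, list(matrix.nodes)
    else:
        rows = np.asarray(matrix, dtype=float)
        labels = list(range(rows.shape[0]))
    if rows.shape[0] < 2:
        raise ValueError("ward_dendrogram: need >= 2 rows")
    return linkage(rows, method="ward"), labels


def dendrogram_to_newick(z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix to a Newick string."""
    tree = to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist - node.left.dist:.6g},{right}:{node.dist - node.right.dist:.6g})"

    return walk(tree) + ";"


# --------------------------------------------------------------------------
# connectivity accumulation

def accumulate_connectivity(
    net: nx.DiGraph, n_bins: int = 10, hub_percentile: float = 99.0
) -> tuple[pd.DataFrame, set]:
    """Per-node in/out arc counts split by the partner node's age bin.

    The [0, 1] nd timeline is coarse-grained into ``n_bins`` equal bins
    (1-based; age 1.0 falls in the last bin).  Returns a long-format frame
    (node, direction, bin, count) and the set of nodes whose combined
    weighted degree strictly exceeds the ``hub_percentile`` of all nodes,
    flagged for labeling.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    def bin_of(age: float) -> int:
        return min(int(age * n_bins) + 1, n_bins)

    counts: dict[tuple, int] = {}
    for u, v in net.edges:
        # u -> v: an outward arc of u toward v's bin, inward arc of v from u's bin
        ku = ("out", u, bin_of(net.nodes[v]["age"]))
        kv = ("in", v, bin_of(net.nodes[u]["age"]))
        counts[ku] = counts.get(ku, 0) + 1
        counts[kv] = counts.get(kv, 0) + 1
    rows = [
        {"node": n, "direction": d, "bin": b, "count": c}
        for (d, n, b), c in sorted(counts.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2]))
    ]
    df = pd.DataFrame(rows, columns=["node", "direction", "bin", "count"])
    degs = combined_weighted_degree(net)
    hubs = set()
    if degs:
        cut = float(np.percentile(list(degs.values()), hub_percentile))
        hubs = {n for n, d in degs.items() if d > cut}
    return df, hubs
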