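import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import ng_oracle, random_aged_bipartite
from efnet.netbuild import EventNetworkSeries, event_series
from efnet.netstats import (
    DegenerateDistributionError,
    accumulate_connectivity,
    clustering_stats,
    degree_vectors,
    dendrogram_to_newick,
    detect_communities,
    fit_power_law,
    generate_reference_network,
    ng_modularity,
    pairwise_modularity_matrix,
    sample_discrete_power_law,
    ward_dendrogram,
)


def _series_of(g):
    if not nx.get_node_attributes(g, "age"):
        nx.set_node_attributes(g, 0.0, "age")
    return EventNetworkSeries(events=[0.0], snapshots=[g])


class TestDegreeVectors:
    def test_star(self):
        g = nx.star_graph(3)
        frames, curve = degree_vectors(_series_of(g), weighted=False)
        df = frames[0].set_index("node")
        assert df.loc[0, "alldegree"] == 3
        assert all(df.loc[i, "alldegree"] == 1 for i in (1, 2, 3))
        assert curve.loc[0, "max_degree"] == 3

    def test_directed_path(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        frames, _ = degree_vectors(_series_of(g), weighted=False)
        df = frames[0].set_index("node")
        assert list(df["outdegree"]) == [1, 1, 0]
        assert list(df["indegree"]) == [0, 1, 1]
        assert (df["alldegree"] == df["indegree"] + df["outdegree"]).all()

    def test_per_event_matches_naive_recount(self):
        bip = random_aged_bipartite(5)
        s = event_series(bip)
        frames, _ = degree_vectors(s, weighted=False)
        for (event, snap), df in zip(s, frames):
            for _, row in df.iterrows():
                assert row["alldegree"] == snap.degree(row["node"])


class TestPowerLawFit:
    def test_mle_recovers_planted_alpha(self):
        x = sample_discrete_power_law(2.5, 5000, seed=0)
        fit = fit_power_law(x, bootstrap_reps=0)
        assert 2.4 <= fit.alpha <= 2.6

    def test_mle_matches_zeta_grid_oracle(self):
        import sympy

        x = sample_discrete_power_law(2.3, 2000, seed=1)
        fit = fit_power_law(x, bootstrap_reps=0)
        slog = float(np.sum(np.log(x)))
        grid = np.arange(1.5, 3.5, 0.005)
        lls = [-len(x) * np.log(float(sympy.N(sympy.zeta(a)))) - a * slog for a in grid]
        assert abs(fit.alpha - grid[int(np.argmax(lls))]) < 0.01

    def test_bootstrap_p_calibrated_under_null(self):
        # data drawn from the fitted family: p >= 0.05 nearly always
        ok = 0
        for seed in range(20):
            x = sample_discrete_power_law(2.5, 1000, seed=100 + seed)
            fit = fit_power_law(x, bootstrap_reps=50, seed=seed)
            ok += fit.ks_p >= 0.05
        assert ok >= 18

    def test_degenerate_vector_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            fit_power_law([3] * 50)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law([1, 2, 3])

    def test_gamma_r2_ranges(self):
        x = sample_discrete_power_law(2.5, 3000, seed=2)
        fit = fit_power_law(x, bootstrap_reps=0)
        assert fit.gamma >= 0
        assert 0 <= fit.r_squared <= 1


class TestSampler:
    def test_support_and_determinism(self):
        x = sample_discrete_power_law(2.0, 500, seed=3)
        assert x.min() >= 1
        assert (x == sample_discrete_power_law(2.0, 500, seed=3)).all()

    def test_pmf_head_matches_zeta(self):
        x = sample_discrete_power_law(2.5, 200_000, seed=4)
        from scipy.special import zeta

        p1 = np.mean(x == 1)
        assert p1 == pytest.approx(1 / zeta(2.5), abs=0.005)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sample_discrete_power_law(1.0, 10)


class TestReferenceNetworks:
    def test_tree_has_zero_clustering(self):
        g = generate_reference_network(1000, "barabasi", 1, seed=0)
        und = g.to_undirected()
        assert nx.average_clustering(und) == 0.0
        assert nx.is_tree(und)

    def test_tail_exponent_near_three(self):
        # preferential attachment's asymptotic P(k) ~ k^-3; the tail MLE
        # (xmin = 3) should land in a band around it
        alphas = []
        for seed in range(5):
            g = generate_reference_network(2000, "barabasi", 1, seed=seed)
            deg = np.array([d for _, d in g.to_undirected().degree()])
            alphas.append(fit_power_law(deg, bootstrap_reps=0, xmin=3).alpha)
        assert 2.5 <= np.mean(alphas) <= 3.5

    def test_seeded_determinism(self):
        g1 = generate_reference_network(200, "barabasi_age", 2, seed=9)
        g2 = generate_reference_network(200, "barabasi_age", 2, seed=9)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_arcs_point_forward_in_time(self):
        g = generate_reference_network(300, "barabasi", 2, seed=1)
        for u, v in g.edges:
            assert g.nodes[u]["age"] <= g.nodes[v]["age"]


class TestClusteringStats:
    def test_triangle_and_path(self):
        tri = nx.complete_graph(3)
        nx.set_node_attributes(tri, 0.0, "age")
        df = clustering_stats(_series_of(tri))
        assert df["c"].iloc[0] == pytest.approx(1.0)
        path = nx.path_graph(3)
        nx.set_node_attributes(path, 0.0, "age")
        assert clustering_stats(_series_of(path))["c"].iloc[0] == pytest.approx(0.0)

    def test_matches_exhaustive_triangle_triad_count(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(20, 0.25, seed=5)
        nx.set_node_attributes(g, 0.0, "age")
        df = clustering_stats(_series_of(g))
        # brute force: per node, triangles among neighbor pairs / possible pairs
        total = 0.0
        for n in g:
            nbrs = list(g.neighbors(n))
            if len(nbrs) < 2:
                continue
            pairs = list(itertools.combinations(nbrs, 2))
            tri = sum(1 for a, b in pairs if g.has_edge(a, b))
            total += tri / len(pairs)
        assert df["c"].iloc[0] == pytest.approx(total / g.number_of_nodes())

    def test_bipartite_reports_absent(self):
        bip = random_aged_bipartite(0)
        df = clustering_stats(event_series(bip))
        assert df["c"].isna().all()


class TestNgModularity:
    def test_trivial_partition_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        nx.set_edge_attributes(g, 1, "weight")
        assert ng_modularity(g, {n: 0 for n in g}) == pytest.approx(0.0)

    def test_two_triangles_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = {n: n // 3 for n in g}
        assert ng_modularity(g, part) == pytest.approx(0.5)

    def test_aged_path_value(self):
        g = nx.Graph()
        g.add_node("L1", age=0.1)
        g.add_node("D1", age=0.1)
        g.add_node("L2", age=0.2)
        g.add_edges_from([("L1", "D1"), ("D1", "L2")])
        part = {"L1": 0.1, "D1": 0.1, "L2": 0.2}
        assert ng_modularity(g, part) == pytest.approx(-0.125)

    def test_matches_bruteforce_oracle_and_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.integers(1, 5))
            part = {node: int(rng.integers(3)) for node in g}
            q = ng_modularity(g, part)
            assert q == pytest.approx(ng_oracle(g, part), abs=1e-12)
            assert -1.0 <= q <= 1.0

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            ng_modularity(g, {0: 0, 1: 0})


class TestCommunities:
    def test_two_triangles_optimum(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part, q = detect_communities(g, "greedy")
        assert len(set(part.values())) == 2
        assert q == pytest.approx(0.5)
        # exhaustive search over all partitions of 6 nodes confirms optimality
        best = max(
            ng_modularity(g, dict(zip(g, labels)))
            for labels in itertools.product(range(3), repeat=6)
        )
        assert q == pytest.approx(best)

    def test_complete_graph_single_community(self):
        part, q = detect_communities(nx.complete_graph(5), "greedy")
        assert len(set(part.values())) == 1
        assert q == pytest.approx(0.0)

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = nx.gnp_random_graph(7, 0.45, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            _, q = detect_communities(g, "greedy")
            best = max(
                ng_modularity(g, dict(zip(g, labels)))
                for labels in itertools.product(range(4), repeat=7)
            )
            assert q <= best + 1e-12

    def test_planted_partition_recovered(self):
        from efnet.synthdata import generate_planted_partition

        g, truth = generate_planted_partition(2, 30, 0.8, 0.05, seed=3)
        part, _ = detect_communities(g, "greedy")
        # agreement up to relabeling (2 blocks)
        agree = sum(
            (part[a] == part[b]) == (truth[a] == truth[b])
            for a, b in itertools.combinations(g, 2)
        )
        assert agree / (len(g) * (len(g) - 1) / 2) >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(nx.empty_graph(3), "greedy")


class TestPairwiseModularityMatrix:
    def test_single_edge_hand_values(self):
        g = nx.Graph()
        g.add_node("A", age=0.0, kind="loop")
        g.add_node("B", age=0.0, kind="domain")
        g.add_edge("A", "B")
        pm = pairwise_modularity_matrix(g, m_nd=1.0)
        assert pm.entries == pytest.approx(np.array([[-0.5, 0.5], [0.5, -0.5]]))
        assert pm.entries.sum() == pytest.approx(0.0, abs=1e-12)

    def test_empty_snapshot_rejected(self):
        g = nx.Graph()
        g.add_node("A", age=0.9, kind="loop")
        with pytest.raises(ValueError):
            pairwise_modularity_matrix(g, event=0.1)

    def test_zero_sum_before_and_after_scaling(self):
        for seed in range(20):
            bip = random_aged_bipartite(seed)
            if bip.number_of_edges() == 0:
                continue
            pm = pairwise_modularity_matrix(bip, m_nd=1.0)
            assert abs(pm.entries.sum()) < 1e-9
            pm2 = pairwise_modularity_matrix(bip, m_nd=7.3)
            assert abs(pm2.entries.sum()) < 1e-9

    def test_scaling_fallback_warns_when_ng_age_zero(self):
        g = nx.Graph()
        g.add_node("A", age=0.0, kind="loop")
        g.add_node("B", age=0.0, kind="domain")
        g.add_edge("A", "B")
        with pytest.warns(UserWarning):
            pm = pairwise_modularity_matrix(g)  # one event: NG_age = 0
        assert pm.m_nd == 1.0


def naive_ward_cophenet(x):
    """O(n^3) Ward clustering; returns the cophenetic distance matrix."""
    x = np.asarray(x, dtype=float)
    clusters = {i: [i] for i in range(len(x))}
    coph = np.zeros((len(x), len(x)))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = x[clusters[a]].mean(axis=0), x[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ma - mb)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


class TestWardDendrogram:
    def test_identical_rows_merge_first_at_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        z, _ = ward_dendrogram(x)
        assert z[0, 2] == pytest.approx(0.0)
        assert set(z[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(0)
        z, _ = ward_dendrogram(rng.normal(size=(12, 4)))
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_matches_naive_ward_oracle(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42)
        x = rng.normal(size=(8, 5))
        z, _ = ward_dendrogram(x)
        got = squareform(cophenet(z))
        assert got == pytest.approx(naive_ward_cophenet(x), rel=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ward_dendrogram(np.ones((1, 3)))

    def test_newick_export(self):
        z, labels = ward_dendrogram(np.eye(4))
        nwk = dendrogram_to_newick(z, labels)
        assert nwk.endswith(";") and nwk.count("(") == 3


class TestAccumulateConnectivity:
    def test_bin_placement(self):
        g = nx.DiGraph()
        g.add_node("a", age=0.05)
        g.add_node("b", age=0.95)
        g.add_edge("a", "b", weight=1)
        df, _ = accumulate_connectivity(g, n_bins=10)
        rec = df.set_index(["node", "direction"])
        assert rec.loc[("b", "in"), "bin"] == 1
        assert rec.loc[("a", "out"), "bin"] == 10

    def test_counts_conserved_and_match_naive_tally(self):
        g = generate_reference_network(60, "barabasi", 2, seed=2)
        df, hubs = accumulate_connectivity(g, n_bins=5)
        for direction in ("in", "out"):
            assert df[df["direction"] == direction]["count"].sum() == g.number_of_edges()
        naive = {}
        for u, v in g.edges:
            b_out = min(int(g.nodes[v]["age"] * 5) + 1, 5)
            naive[(u, "out", b_out)] = naive.get((u, "out", b_out), 0) + 1
        for (n, d, b), c in naive.items():
            row = df[(df["node"] == n) & (df["direction"] == d) & (df["bin"] == b)]
            assert int(row["count"].iloc[0]) == c
        assert all(h in g for h in hubs)
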