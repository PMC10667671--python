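"""Co-occurrence networks: construction, subgraphs, topology, comparisons."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import conftest
from coresat import (
    CommunityTable,
    build_network,
    compare_metrics_by_period,
    network_node_filter,
    occupancy_sets,
    partition_taxa,
    sample_subnetwork,
    subnetwork_metrics,
    topological_metrics,
)
from coresat.networks import exhaustive_best_modularity


def table(counts):
    counts = np.asarray(counts)
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(counts.shape[0])],
            columns=[f"t{j}" for j in range(counts.shape[1])],
        )
    )


class TestNodeFilter:
    def test_equals_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(12, 40))
        counts[:, 0] = 1
        t = table(counts)
        periods = ["before"] * 4 + ["mixing"] * 4 + ["after"] * 4
        got = set(network_node_filter(t, periods, min_rel_abund=0.01))
        rel = t.relative_abundance()
        expect = set()
        for tx in t.taxa:
            in_all = all(
                (counts[np.asarray(periods) == p, list(t.taxa).index(tx)] > 0).any()
                for p in ("before", "mixing", "after")
            )
            if in_all and rel[tx].mean() >= 0.01:
                expect.add(tx)
        assert got == expect


class TestBuildNetwork:
    def test_bh_adjustment_equals_brute_force(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        got = multipletests(p, method="fdr_bh")[1]
        # brute-force BH step-up: sort ascending, p_i * m / i, enforce
        # monotonicity from the largest down, cap at 1
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        adj = np.minimum(adj, 1.0)
        expect = np.empty(m)
        expect[order] = adj
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_independent_taxa_give_no_false_edges(self):
        # FDR at 0.01 plus |rho| >= 0.8 on n=34: false edges are essentially
        # impossible for independent Gaussian taxa
        false_edges = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            counts = rng.integers(1, 1000, size=(34, 50))
            net = build_network(table(counts))
            false_edges += net.graph.number_of_edges()
        # 122_500 independent pairs; the compositional (relative-abundance)
        # transform can push an occasional borderline pair over |rho|=0.8
        assert false_edges <= 2

    def test_planted_correlation_is_found(self):
        rng = np.random.default_rng(2)
        base = rng.integers(100, 1000, size=34)
        counts = np.column_stack(
            [base, base + rng.integers(0, 5, 34)]
            + [rng.integers(1, 1000, size=34) for _ in range(8)]
        )
        net = build_network(table(counts))
        assert net.graph.has_edge("t0", "t1")
        e = net.graph.edges["t0", "t1"]
        assert abs(e["rho"]) >= 0.8 and e["p_adj"] < 0.01

    def test_thresholds_respected(self, surface_table, default_dataset):
        periods = default_dataset.truth["periods"]
        core = surface_table.subset_taxa(
            occupancy_sets(partition_taxa(surface_table))["core"]
        )
        nt = core.subset_taxa(network_node_filter(core, periods))
        net = build_network(nt)
        assert net.graph.number_of_edges() > 0
        for _, _, d in net.graph.edges(data=True):
            assert abs(d["rho"]) >= 0.8
            assert d["p_adj"] < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            build_network(table(np.ones((4, 6), int)))


class TestSampleSubnetwork:
    def test_equals_brute_force_induced_subgraph(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=34)
        counts = np.column_stack(
            [np.abs(base * s + rng.normal(0, 0.05, 34)) * 100 + 1 for s in (1, 1, -1, -1, 1)]
        ).astype(int)
        t = table(counts)
        net = build_network(t)
        for i in range(5):
            mask = rng.random(5) < 0.6
            sample_counts = pd.Series(mask.astype(int), index=t.taxa)
            sub = sample_subnetwork(net, sample_counts)
            present = [tx for tx in net.nodes if sample_counts[tx] > 0]
            expect = net.graph.subgraph(present)
            assert set(sub.nodes) == set(expect.nodes)
            assert {frozenset(e) for e in sub.edges} == {
                frozenset(e) for e in expect.edges
            }


class TestTopologicalMetrics:
    def test_star_graph_closed_forms(self):
        m = topological_metrics(nx.star_graph(4))  # K_{1,4}
        assert m["node_count"] == 5
        assert m["edge_count"] == 4
        assert m["density"] == pytest.approx(0.4)
        assert m["average_path_length"] == pytest.approx(1.6)
        assert m["betweenness_centralization"] == pytest.approx(1.0)

    def test_two_triangles_modularity(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        m = topological_metrics(g)
        best_q, best_parts = exhaustive_best_modularity(g)
        # greedy CNM finds the optimum here: the two triangles
        assert m["modularity"] == pytest.approx(best_q, abs=1e-12)
        # Q = sum_c (e_c/m - (d_c/2m)^2) = 2*(3/6 - (6/12)^2) = 1/2
        assert m["modularity"] == pytest.approx(0.5, abs=1e-12)
        assert {frozenset(p) for p in best_parts} == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }

    def test_greedy_matches_exhaustive_on_random_graphs(self):
        rng = np.random.default_rng(4)
        agree = 0
        for _ in range(20):
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            got = topological_metrics(g)["modularity"]
            best, _ = exhaustive_best_modularity(g)
            assert got <= best + 1e-12
            agree += got == pytest.approx(best, abs=1e-9)
        assert agree >= 10  # greedy is optimal on most small instances

    def test_disconnected_apl_over_connected_pairs(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        m = topological_metrics(g)
        # four connected pairs, all at distance 1
        assert m["average_path_length"] == pytest.approx(1.0)

    def test_degenerate_graphs(self):
        m = topological_metrics(nx.empty_graph(2))
        assert np.isnan(m["average_path_length"])
        assert np.isnan(m["modularity"])


class TestPeriodComparison:
    def test_exact_p_three_groups_of_three(self):
        rng = np.random.default_rng(5)
        metrics = pd.DataFrame(
            {"density": rng.random(9)}, index=[f"s{i}" for i in range(9)]
        )
        periods = ["before"] * 3 + ["mixing"] * 3 + ["after"] * 3
        out = compare_metrics_by_period(metrics, periods)
        # exhaustive-permutation oracle for the KW statistic
        vals = metrics["density"].to_numpy()
        H_obs = stats.kruskal(vals[:3], vals[3:6], vals[6:]).statistic
        # H is invariant to within-group order, so enumerating the
        # C(9,3)*C(6,3) = 1680 set partitions is exhaustive
        count, total = 0, 0
        idx = set(range(9))
        for g1 in itertools.combinations(range(9), 3):
            rest = sorted(idx - set(g1))
            for g2 in itertools.combinations(rest, 3):
                g3 = sorted(set(rest) - set(g2))
                H = stats.kruskal(vals[list(g1)], vals[list(g2)], vals[g3]).statistic
                count += H >= H_obs - 1e-12
                total += 1
        assert total == 1680
        assert out["density"]["p"] == pytest.approx(count / total, abs=0.03)

    def test_density_letter_pattern_majority(self):
        # mixing-period subnetworks differ from before, while after shares
        # before's letter (surface recovery) — majority across seeds
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            ds = conftest.dataset(seed)
            tab = conftest.prepared(seed, "surface")
            periods = ds.truth["periods"]
            core = tab.subset_taxa(occupancy_sets(partition_taxa(tab))["core"])
            nt = core.subset_taxa(network_node_filter(core, periods))
            net = build_network(nt)
            res = compare_metrics_by_period(subnetwork_metrics(net, nt), periods)
            letters = res["density"]["letters"]
            if letters["mixing"] != letters["before"] and set(letters["after"]) & set(
                letters["before"]
            ):
                hits += 1
        assert hits > n_seeds // 2
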