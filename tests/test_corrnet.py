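import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cephnet as cn
from cephnet import corrnet
from cephnet.measure import MeasurementTable
from conftest import random_correlation


def _table(df):
    return MeasurementTable(df, units={c: "mm" for c in df.columns},
                            numbers={c: i + 1 for i, c in enumerate(df.columns)})


class TestPearsonMatrix:
    def test_self_correlation_is_one(self, preset_corr):
        assert np.allclose(np.diag(preset_corr.r), 1.0)

    def test_affine_columns(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "up": 2 * x + 3, "down": -2 * x + 3})
        cm = corrnet.pearson_matrix(_table(df))
        assert cm.r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cm.r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        # 5-row toy table against the direct covariance formula
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.5, 5.0, 4.0, 8.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        cm = corrnet.pearson_matrix(_table(pd.DataFrame({"x": x, "y": y})))
        assert cm.r[0, 1] == pytest.approx(num / den, abs=1e-12)

    def test_constant_column_named_in_error(self, rng):
        df = pd.DataFrame({"ok": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            corrnet.pearson_matrix(_table(df))

    def test_too_few_rows(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="3 subjects"):
            corrnet.pearson_matrix(_table(df))


class TestPairCount:
    @pytest.mark.parametrize("v,expected", [(65, 2080), (14, 91), (2, 1), (10, 45)])
    def test_values(self, v, expected):
        assert corrnet.pair_count(v) == expected

    def test_too_small(self):
        with pytest.raises(ValueError):
            corrnet.pair_count(1)

    def test_matches_upper_triangle_of_matrix(self, preset_corr):
        assert preset_corr.abs_weights().size == corrnet.pair_count(65)


class TestWeightDistribution:
    def test_identity_matrix(self):
        cm = cn.CorrelationMatrix(list("abcd"), np.eye(4), 10)
        dist = corrnet.weight_distribution(cm)
        assert np.all(dist.weights == 0.0)
        assert dist.fraction_at_or_above[0.4] == 0.0

    def test_all_ones_matrix(self):
        cm = cn.CorrelationMatrix(list("abc"), np.ones((3, 3)), 10)
        dist = corrnet.weight_distribution(cm)
        assert dist.fraction_at_or_above[0.8] == 1.0

    def test_fractions_monotone_on_preset(self, preset_corr):
        dist = corrnet.weight_distribution(preset_corr, cutoffs=(0.4, 0.6, 0.8))
        f = [dist.fraction_at_or_above[c] for c in (0.4, 0.6, 0.8)]
        assert f[0] >= f[1] >= f[2] > 0

    def test_fraction_equals_edge_count_over_pairs(self, preset_corr):
        dist = corrnet.weight_distribution(preset_corr, cutoffs=(0.4, 0.6, 0.8))
        v = len(preset_corr.variables)
        for c in (0.4, 0.6, 0.8):
            g = corrnet.threshold_graph(preset_corr, c)
            assert dist.fraction_at_or_above[c] == g.number_of_edges() / corrnet.pair_count(v)

    def test_direct_count_oracle(self, preset_corr):
        w = preset_corr.abs_weights()
        dist = corrnet.weight_distribution(preset_corr, cutoffs=(0.5,))
        assert dist.fraction_at_or_above[0.5] == np.sum(w >= 0.5) / w.size

    def test_cpdf_monotone_ends_at_one(self, preset_corr):
        dist = corrnet.weight_distribution(preset_corr)
        xs = np.linspace(0, 1, 21)
        vals = [dist.cpdf(x) for x in xs]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0

    def test_histogram_counts_sum_to_pairs(self, preset_corr):
        dist = corrnet.weight_distribution(preset_corr)
        assert dist.counts.sum() == corrnet.pair_count(65)


class TestThresholdGraph:
    def test_above_max_gives_edgeless_graph(self, rng):
        cm = random_correlation(rng, 6)
        cutoff = min(0.999, cm.abs_weights().max() + 1e-6)
        g = corrnet.threshold_graph(cm, cutoff)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 0

    def test_nesting(self, rng):
        for _ in range(10):
            cm = random_correlation(rng, 8)
            e8 = set(corrnet.threshold_graph(cm, 0.8).edges)
            e6 = set(corrnet.threshold_graph(cm, 0.6).edges)
            e4 = set(corrnet.threshold_graph(cm, 0.4).edges)
            assert e8 <= e6 <= e4

    def test_inclusive_cutoff_keeps_ties(self):
        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        cm = cn.CorrelationMatrix(["a", "b"], r, 10)
        assert corrnet.threshold_graph(cm, 0.6).has_edge("a", "b")

    def test_edge_count_matches_brute_force(self, rng):
        cm = random_correlation(rng, 6)
        cutoff = 0.3
        expected = sum(
            1 for i in range(6) for j in range(i + 1, 6)
            if abs(cm.r[i, j]) >= cutoff)
        assert corrnet.threshold_graph(cm, cutoff).number_of_edges() == expected

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_cutoff_out_of_range(self, preset_corr, bad):
        with pytest.raises(ValueError):
            corrnet.threshold_graph(preset_corr, bad)

    def test_edge_weight_is_abs_r(self, preset_corr):
        g = corrnet.threshold_graph(preset_corr, 0.6)
        for u, v, d in g.edges(data=True):
            assert d["weight"] == pytest.approx(abs(d["r"]))
            assert d["weight"] >= 0.6


def _dfs_components(graph):
    """Independent DFS oracle for connected components."""
    seen, comps = set(), []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(graph.neighbors(n))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestConnectedComponents:
    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(5)
        ca = corrnet.connected_components(g)
        assert len(ca.clusters()) == 0
        assert len(ca.isolated()) == 5

    def test_two_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        ca = corrnet.connected_components(g)
        assert len(ca.clusters()) == 2

    def test_random_graphs_vs_dfs_oracle(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.15, seed=int(rng.integers(1e6)))
            ca = corrnet.connected_components(g)
            got = {frozenset(m) for m in ca.components.values()}
            assert got == _dfs_components(g)

    def test_partition_covers_all_nodes(self, preset_corr):
        g = corrnet.threshold_graph(preset_corr, 0.8)
        ca = corrnet.connected_components(g)
        assert set(ca.labels) == set(g.nodes)
        assert sum(ca.sizes.values()) == g.number_of_nodes()


class TestIsClique:
    def test_single_node_and_edge(self):
        g = nx.Graph([("a", "b")])
        assert corrnet.is_clique(g, ["a"]) == (True, [])
        assert corrnet.is_clique(g, ["a", "b"]) == (True, [])

    def test_triangle_minus_one_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        ok, missing = corrnet.is_clique(g, ["a", "b", "c"])
        assert not ok
        assert missing == [("a", "c")]

    def test_unknown_node_raises(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(KeyError):
            corrnet.is_clique(g, ["a", "z"])

    def test_all_4_subsets_vs_exhaustive_oracle(self, rng):
        g = nx.gnp_random_graph(10, 0.5, seed=99)
        for sub in itertools.combinations(g.nodes, 4):
            ok, missing = corrnet.is_clique(g, sub)
            expected = all(g.has_edge(u, v) for u, v in itertools.combinations(sub, 2))
            assert ok == expected
            assert ok == (len(missing) == 0)


class TestOverlayClusters:
    def test_all_singletons_unclustered(self, rng):
        cm = random_correlation(rng, 5)
        base = corrnet.threshold_graph(cm, 0.1)
        fine = corrnet.ClusterAssignment(
            labels={v: i for i, v in enumerate(cm.variables)},
            sizes={i: 1 for i in range(5)})
        g = corrnet.overlay_clusters(base, fine)
        assert all(g.nodes[n]["cluster"] == corrnet.UNCLUSTERED for n in g.nodes)

    def test_three_node_cluster_shares_label(self, rng):
        cm = random_correlation(rng, 5)
        base = corrnet.threshold_graph(cm, 0.1)
        labels = {v: (0 if i < 3 else i) for i, v in enumerate(cm.variables)}
        fine = corrnet.ClusterAssignment(labels=labels, sizes={0: 3, 3: 1, 4: 1})
        g = corrnet.overlay_clusters(base, fine)
        got = {g.nodes[v]["cluster"] for v in cm.variables[:3]}
        assert got == {"C1"}
        assert g.nodes[cm.variables[4]]["cluster"] == corrnet.UNCLUSTERED

    def test_variable_mismatch_raises(self, rng):
        cm = random_correlation(rng, 4)
        base = corrnet.threshold_graph(cm, 0.1)
        fine = corrnet.ClusterAssignment(labels={"other": 0}, sizes={0: 1})
        with pytest.raises(ValueError, match="differ"):
            corrnet.overlay_clusters(base, fine)

    def test_preset_clusters_connected_in_base_graph(self, preset_corr):
        base = corrnet.threshold_graph(preset_corr, 0.6)
        fine = corrnet.connected_components(corrnet.threshold_graph(preset_corr, 0.8))
        g = corrnet.overlay_clusters(base, fine)
        labels = nx.get_node_attributes(g, "cluster")
        for label in set(labels.values()) - {corrnet.UNCLUSTERED}:
            members = [n for n, l in labels.items() if l == label]
            assert nx.is_connected(g.subgraph(members))


class TestSubnetworkCompare:
    def test_own_edges_zero_discrepancies(self, preset_corr):
        subset = preset_corr.variables[:14]
        own = corrnet.threshold_graph(preset_corr.submatrix(subset), 0.6).edges
        report = corrnet.subnetwork_compare(preset_corr, subset, 0.6, list(own))
        assert report["extra"] == [] and report["missing"] == []
        assert len(report["matched"]) == len(own)

    def test_one_toggled_pair_one_discrepancy(self, preset_corr):
        subset = ["SNA", "SNB", "ANB", "FMA"]
        own = [tuple(sorted(e)) for e in
               corrnet.threshold_graph(preset_corr.submatrix(subset), 0.6).edges]
        assert own, "need at least one edge to toggle"
        toggled = own[1:] + ([] if len(own) > 1 else [])
        report = corrnet.subnetwork_compare(preset_corr, subset, 0.6, toggled)
        assert len(report["missing"]) == 0
        assert report["extra"] == [own[0]]

    def test_unknown_variable_raises(self, preset_corr):
        with pytest.raises(KeyError):
            corrnet.subnetwork_compare(preset_corr, ["nope"], 0.6, [])
        with pytest.raises(KeyError):
            corrnet.subnetwork_compare(preset_corr, ["SNA", "SNB"], 0.6,
                                       [("SNA", "nope")])

    def test_14_variable_subset_vs_recompute_oracle(self, preset_table, preset_corr):
        subset = preset_corr.variables[10:24]
        report = corrnet.subnetwork_compare(preset_corr, subset, 0.6, [])
        # brute-force recomputation straight from the data columns
        x = preset_table.data[list(subset)].to_numpy()
        expected = set()
        for i in range(14):
            for j in range(i + 1, 14):
                r = np.corrcoef(x[:, i], x[:, j])[0, 1]
                if abs(r) >= 0.6:
                    expected.add(tuple(sorted((subset[i], subset[j]))))
        assert set(report["extra"]) == expected


class TestMatrixProperties:
    def test_affine_invariance_of_topology(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
        cm1 = corrnet.pearson_matrix(_table(df))
        scaled = df * np.array([2.0, -3.0, 0.5, 10.0, 1.0, -1.0]) + 5.0
        cm2 = corrnet.pearson_matrix(_table(scaled))
        assert np.abs(np.abs(cm1.r) - np.abs(cm2.r)).max() < 1e-12
        for c in (0.2, 0.5):
            assert set(corrnet.threshold_graph(cm1, c).edges) == \
                set(corrnet.threshold_graph(cm2, c).edges)

    def test_permutation_equivariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        cm1 = corrnet.pearson_matrix(_table(df))
        perm = ["c", "a", "e", "b", "d"]
        cm2 = corrnet.pearson_matrix(_table(df[perm]))
        g1 = corrnet.threshold_graph(cm1, 0.1)
        g2 = corrnet.threshold_graph(cm2, 0.1)
        assert {tuple(sorted(e)) for e in g1.edges} == {tuple(sorted(e)) for e in g2.edges}

    def test_matrix_csv_roundtrip(self, preset_corr, tmp_path):
        path = tmp_path / "corr.csv"
        preset_corr.to_csv(path)
        back = cn.CorrelationMatrix.from_csv(path, n_subjects=preset_corr.n_subjects)
        assert back.variables == preset_corr.variables
        assert np.abs(back.r - preset_corr.r).max() < 1e-12

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cn.CorrelationMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]), 5)
        with pytest.raises(ValueError, match="diagonal"):
            cn.CorrelationMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]), 5)
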