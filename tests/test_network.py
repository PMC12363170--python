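import networkx as nx
import numpy as np
import pandas as pd
import pytest

from guildnet import (
    AbundanceTable,
    build_network,
    detect_modules,
    eigenvector_centrality,
    ko_module_correlates,
    modularity_score,
    module_relative_abundance,
    sample_network_properties,
    sample_subnetwork,
)
from guildnet.network import ModulePartition


def edge_frame(pairs):
    return pd.DataFrame(
        {
            "feature_a": [a for a, b in pairs],
            "feature_b": [b for a, b in pairs],
            "rho": [0.9] * len(pairs),
        }
    )


def brute_force_modularity(g, partition):
    """Q as the O(n^2) pairwise double sum over the adjacency matrix."""
    nodes = list(g.nodes)
    m = g.number_of_edges()
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if partition[u] == partition[v]:
                q += a[i, j] - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


class TestBuildNetwork:
    def test_isolated_nodes_kept(self):
        g = build_network(edge_frame([]), ["a", "b", "c", "d", "e"])
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edge_frame([("a", "b"), ("b", "a")]), ["a", "b"])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            build_network(edge_frame([("a", "a")]), ["a"])

    def test_planted_blocks_become_components(self):
        pairs = [("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")]
        g = build_network(edge_frame(pairs), ["a", "b", "c", "x", "y", "z"])
        comps = sorted(sorted(c) for c in nx.connected_components(g))
        assert comps == [["a", "b", "c"], ["x", "y", "z"]]


class TestModularityScore:
    def test_single_community_is_zero(self):
        g = nx.gnp_random_graph(12, 0.4, seed=1)
        assert modularity_score(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0)

    def test_two_triangles_give_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = {n: (0 if n < 3 else 1) for n in g.nodes}
        assert modularity_score(g, part) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        partition = {node: int(rng.integers(0, 4)) for node in g.nodes}
        assert modularity_score(g, partition) == pytest.approx(
            brute_force_modularity(g, partition), abs=1e-12
        )

    def test_matches_networkx_oracle(self):
        g = nx.gnp_random_graph(20, 0.25, seed=3)
        partition = {n: n % 3 for n in g.nodes}
        communities = [{n for n in g.nodes if n % 3 == c} for c in range(3)]
        assert modularity_score(g, partition) == pytest.approx(
            nx.community.modularity(g, communities), abs=1e-12
        )

    def test_edgeless_graph_defined_as_zero(self):
        g = nx.empty_graph(4)
        with pytest.warns(UserWarning, match="edgeless"):
            assert modularity_score(g, {n: 0 for n in g.nodes}) == 0.0

    def test_partition_must_cover_nodes(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="cover"):
            modularity_score(g, {0: 0, 1: 0})


class TestDetectModules:
    @staticmethod
    def two_cliques():
        g = nx.Graph()
        for base in ("a", "b"):
            members = [f"{base}{i}" for i in range(5)]
            g.add_edges_from(
                (members[i], members[j]) for i in range(5) for j in range(i + 1, 5)
            )
        g.add_edge("a0", "b0")  # single bridge keeps it one component
        return g

    def test_two_cliques_found_and_labelled(self):
        part = detect_modules(self.two_cliques())
        modules = part.modules()
        groups = sorted(tuple(v) for v in modules.values())
        assert groups == [tuple(f"a{i}" for i in range(5)), tuple(f"b{i}" for i in range(5))]
        assert sorted(part.major_labels.values()) == ["M1", "M2"]

    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(12)
        part = detect_modules(g)
        assert len(set(part.membership.values())) == 12
        assert part.major_labels == {}  # singletons are each <10% of 12 nodes

    def test_major_label_threshold_is_strict(self):
        # 10 nodes: a 1-node module is exactly 10% and must NOT be labelled
        g = nx.empty_graph(0)
        g.add_nodes_from(range(10))
        g.add_edges_from((i, j) for i in range(9) for j in range(i + 1, 9))
        part = detect_modules(g)
        labelled = {part.label_of(n) for n in range(9)}
        assert labelled == {"M1"}
        assert part.label_of(9) == "other"

    def test_invariant_to_node_input_order(self):
        g1 = self.two_cliques()
        g2 = nx.Graph()
        g2.add_nodes_from(reversed(list(g1.nodes)))
        g2.add_edges_from(reversed([tuple(reversed(e)) for e in g1.edges]))
        p1 = detect_modules(g1)
        p2 = detect_modules(g2)
        assert p1.membership == p2.membership
        assert p1.major_labels == p2.major_labels

    def test_reported_q_matches_modularity_score(self):
        g = nx.gnp_random_graph(25, 0.15, seed=7)
        part = detect_modules(g)
        assert part.modularity == pytest.approx(
            modularity_score(g, part.membership), abs=1e-12
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_modules(nx.Graph())


class TestSampleSubnetwork:
    def path_graph(self):
        return build_network(edge_frame([("A", "B"), ("B", "C")]), ["A", "B", "C"])

    def test_all_present_is_identity(self):
        g = self.path_graph()
        sub = sample_subnetwork(g, {"A": 0.2, "B": 0.3, "C": 0.5})
        assert set(sub.nodes) == set(g.nodes) and set(sub.edges) == set(g.edges)

    def test_single_present_node(self):
        sub = sample_subnetwork(self.path_graph(), {"B": 1.0})
        assert list(sub.nodes) == ["B"] and sub.number_of_edges() == 0

    def test_middle_node_absent_splits_path(self):
        sub = sample_subnetwork(self.path_graph(), {"A": 0.5, "C": 0.5})
        assert sorted(sub.nodes) == ["A", "C"] and sub.number_of_edges() == 0

    def test_monotone_in_presence(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        abund = {n: float(rng.random() > 0.5) for n in g.nodes}
        sub1 = sample_subnetwork(g, abund)
        absent = [n for n in g.nodes if abund[n] == 0]
        if absent:
            abund2 = {**abund, absent[0]: 1.0}
            sub2 = sample_subnetwork(g, abund2)
            assert set(sub1.edges) <= set(sub2.edges)


class TestEigenvectorCentrality:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(int(rng.integers(5, 50)), 0.15, seed=seed)
        cent = eigenvector_centrality(g)
        comps = sorted(
            nx.connected_components(g), key=lambda c: (-len(c), min(str(x) for x in c))
        )
        comp = sorted(comps[0], key=str)
        if len(comp) < 2:
            return
        a = nx.to_numpy_array(g, nodelist=comp, weight=None)
        _, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, -1])
        lead /= lead.max()
        for node, expect in zip(comp, lead):
            assert cent[node] == pytest.approx(expect, abs=1e-8)

    def test_complete_graph_all_ones(self):
        cent = eigenvector_centrality(nx.complete_graph(4))
        assert all(v == pytest.approx(1.0) for v in cent.values())

    def test_nodes_outside_largest_component_get_zero(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        cent = eigenvector_centrality(g)
        assert cent[3] == 0.0 and cent[4] == 0.0
        assert cent[1] == 1.0


class TestSampleNetworkProperties:
    def make_table(self, data, samples):
        df = pd.DataFrame(data, columns=samples)
        df.index = [f"n{i}" for i in range(df.shape[0])]
        return AbundanceTable(df, kind="relative")

    def test_three_node_path_arithmetic(self):
        g = build_network(edge_frame([("n0", "n1"), ("n1", "n2")]), ["n0", "n1", "n2"])
        table = self.make_table([[0.2], [0.3], [0.5]], ["s1"])
        stats = sample_network_properties(g, table)
        assert stats.loc["s1", "mean_degree"] == pytest.approx(4.0 / 3.0)
        assert stats.loc["s1", "linkage_density"] == pytest.approx(4.0 / 9.0)

    def test_complete_graph_centrality_is_one(self):
        nodes = [f"n{i}" for i in range(4)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        g = build_network(edge_frame(pairs), nodes)
        table = self.make_table([[0.25]] * 4, ["s1"])
        stats = sample_network_properties(g, table)
        assert stats.loc["s1", "centrality"] == pytest.approx(1.0)

    def test_degenerate_subnetworks_report_zeros(self):
        nodes = [f"n{i}" for i in range(5)]
        g = build_network(edge_frame([]), nodes)
        table = self.make_table([[0.2]] * 5, ["s1"])
        stats = sample_network_properties(g, table)
        row = stats.loc["s1"]
        assert row["degenerate"]
        assert row[["modularity", "mean_degree", "linkage_density", "centrality"]].eq(0).all()

    def test_all_present_sample_equals_global_statistics(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(12)})
        edges = pd.DataFrame(
            {"feature_a": [u for u, v in g.edges], "feature_b": [v for u, v in g.edges],
             "rho": 0.8},
        )
        gg = build_network(edges, sorted(g.nodes))
        table = self.make_table([[1.0 / 12]] * 12, ["all"])
        stats = sample_network_properties(gg, table)
        part = detect_modules(gg)
        cent = eigenvector_centrality(gg)
        assert stats.loc["all", "n_edges"] == gg.number_of_edges()
        assert stats.loc["all", "modularity"] == part.modularity
        assert stats.loc["all", "centrality"] == pytest.approx(
            np.mean(list(cent.values()))
        )


class TestModuleRelativeAbundance:
    def _partition(self):
        membership = {"a1": 0, "a2": 0, "b1": 1, "b2": 1, "c": 2}
        return ModulePartition(
            membership=membership, major_labels={0: "M1", 1: "M2"}, modularity=0.3
        )

    def _table(self):
        df = pd.DataFrame(
            {
                "s1": [0.1, 0.2, 0.3, 0.1, 0.05],
                "s2": [0.0, 0.0, 0.5, 0.2, 0.1],
                "s3": [0.3, 0.1, 0.0, 0.0, 0.2],
            },
            index=["a1", "a2", "b1", "b2", "c"],
        )
        return AbundanceTable(df, kind="relative")

    def test_hand_summed_fixture(self):
        out = module_relative_abundance(self._partition(), self._table())
        assert out.loc["M1", "s1"] == pytest.approx(0.3)
        assert out.loc["M2", "s2"] == pytest.approx(0.7)
        assert out.loc["other", "s3"] == pytest.approx(0.2)

    def test_zero_member_sample(self):
        out = module_relative_abundance(self._partition(), self._table())
        assert out.loc["M1", "s2"] == 0.0

    def test_additivity_with_other(self):
        table = self._table()
        out = module_relative_abundance(self._partition(), table)
        totals = table.data.sum(axis=0)
        assert np.allclose(out.sum(axis=0), totals)


class TestKoModuleCorrelates:
    def _modules(self, rng, n=100):
        samples = [f"s{i}" for i in range(n)]
        return pd.DataFrame(rng.random((4, n)) + 0.1, index=list("WXYZ"), columns=samples)

    def test_monotone_transform_retained_with_rho_one(self, rng):
        mods = self._modules(rng)
        ko = AbundanceTable(
            pd.DataFrame(
                {"K1": np.exp(mods.loc["W"]), "K2": rng.random(100) + 0.1}
            ).T.set_axis(mods.columns, axis=1),
            kind="counts",
        )
        out = ko_module_correlates(ko, mods)
        hit = out[(out.ko == "K1") & (out.module == "W")]
        assert len(hit) == 1 and hit.iloc[0].rho == pytest.approx(1.0)

    def test_abundance_filter_precedes_correlation(self, rng):
        mods = self._modules(rng)
        strong = mods.loc["W"].to_numpy()
        weak = strong * 1e-9  # perfectly correlated but vanishing abundance
        bulk = np.full(100, 1e6)
        df = pd.DataFrame([weak, bulk], index=["K_tiny", "K_bulk"], columns=mods.columns)
        out = ko_module_correlates(AbundanceTable(df, kind="counts"), mods)
        assert "K_tiny" not in set(out.ko)

    def test_null_retention_near_nominal_level(self):
        """Independent KOs cross the |rho|>0.5, p<0.05 double filter at well
        below the nominal 5% rate."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mods = self._modules(rng)
            df = pd.DataFrame(
                rng.random((50, 100)) + 0.1,
                index=[f"K{i}" for i in range(50)],
                columns=mods.columns,
            )
            out = ko_module_correlates(AbundanceTable(df, kind="counts"), mods)
            rates.append(len(out) / (50 * 4))
        assert np.mean(rates) <= 0.05

    def test_too_few_shared_samples_rejected(self, rng):
        mods = self._modules(rng, n=4)
        df = pd.DataFrame(
            rng.random((3, 4)), index=["K1", "K2", "K3"], columns=mods.columns
        )
        with pytest.raises(ValueError, match="shared samples"):
            ko_module_correlates(AbundanceTable(df, kind="counts"), mods)


class TestGlobalPartitionMode:
    def test_global_partition_scores_restricted_assignment(self):
        pairs = [("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")]
        g = build_network(edge_frame(pairs), ["a", "b", "c", "x", "y", "z"])
        part = detect_modules(g)
        table = AbundanceTable(
            pd.DataFrame({"s1": [0.2, 0.2, 0.2, 0.2, 0.2, 0.0]},
                         index=["a", "b", "c", "x", "y", "z"]),
            kind="relative",
        )
        stats = sample_network_properties(g, table, global_partition=part)
        sub = sample_subnetwork(g, table.data["s1"])
        expected = modularity_score(sub, {n: part.membership[n] for n in sub})
        assert stats.loc["s1", "modularity"] == expected
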