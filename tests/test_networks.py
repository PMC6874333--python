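import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nbbd import (OTUTable, build_mb, build_proxi, build_rmt, build_sparcc,
                  pearson_matrix, read_edge_list, sample_counts,
                  sparcc_correlations, write_edge_list)


def table_from(arrays: dict, n=None) -> OTUTable:
    df = pd.DataFrame(arrays)
    df.index = [f"s{i}" for i in range(len(df))]
    return OTUTable(df.astype(float))


class TestPearsonMatrix:
    def test_duplicated_taxon_has_unit_correlation(self):
        t = table_from({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [4, 1, 3, 2]})
        r = pearson_matrix(t)
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        t = table_from({"x": [1, 2, 3], "y": [3, 2, 1]})
        assert pearson_matrix(t).loc["x", "y"] == pytest.approx(-1.0)

    def test_too_few_samples_rejected(self):
        t = table_from({"x": [1, 2], "y": [3, 1]})
        with pytest.raises(ValueError, match="3 samples"):
            pearson_matrix(t)

    def test_constant_taxon_gets_zero_not_nan(self):
        t = table_from({"a": [1, 2, 3, 4], "flat": [2, 2, 2, 2]})
        r = pearson_matrix(t)
        assert r.loc["a", "flat"] == 0.0
        assert r.loc["flat", "flat"] == 1.0

    def test_log_transform_replaces_zeros(self):
        t = table_from({"a": [0, 2, 3, 4], "b": [1, 2, 0, 4]})
        r = pearson_matrix(t, log_transform=True, pseudo_count=1.0)
        assert np.isfinite(r.to_numpy()).all()


class TestProxi:
    def test_strongest_pair_linked_at_k1(self):
        rng = np.random.default_rng(0)
        x1 = rng.random(30)
        t = table_from({"x1": x1, "x2": 2 * x1, "x3": rng.random(30)})
        g = build_proxi(t, k_neighbors=1)
        assert g.has_edge("x1", "x2")

    def test_all_neighbors_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        t = table_from({f"t{i}": rng.random(20) for i in range(5)})
        g = build_proxi(t, k_neighbors=4)
        assert g.number_of_edges() == 10

    def test_min_degree_at_least_k_under_union_rule(self):
        rng = np.random.default_rng(2)
        t = table_from({f"t{i}": rng.random(25) for i in range(12)})
        g = build_proxi(t, k_neighbors=3)
        assert min(dict(g.degree()).values()) >= 3

    def test_negating_a_taxon_leaves_edges_unchanged(self):
        rng = np.random.default_rng(3)
        data = {f"t{i}": rng.random(25) for i in range(8)}
        g1 = build_proxi(table_from(data))
        flipped = dict(data)
        flipped["t3"] = 1.0 - np.asarray(flipped["t3"])  # reflects, |r| kept
        g2 = build_proxi(table_from(flipped))
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))

    def test_mutual_rule_is_subset_of_union(self):
        rng = np.random.default_rng(4)
        t = table_from({f"t{i}": rng.random(30) for i in range(10)})
        union = set(map(frozenset, build_proxi(t, 3, "union").edges()))
        mutual = set(map(frozenset, build_proxi(t, 3, "mutual").edges()))
        assert mutual <= union


@pytest.fixture(scope="module")
def null_table():
    g = nx.relabel_nodes(nx.empty_graph(40), {i: f"t{i:02d}" for i in range(40)})
    return sample_counts(g, 500, depth=10_000, zero_inflation=0.0, seed=3)


@pytest.fixture(scope="module")
def group_table(default_benchmark):
    from nbbd import split_by_phenotype

    return split_by_phenotype(default_benchmark.table)[0]


class TestSparcc:
    def test_independent_taxa_yield_sparse_network(self, null_table):
        g = build_sparcc(null_table)
        n = null_table.n_taxa
        assert g.number_of_edges() / (n * (n - 1) / 2) < 0.05

    def test_compositional_scale_invariance(self, null_table):
        rho1 = sparcc_correlations(null_table).to_numpy()
        scaled = null_table.data.copy()
        scaled.iloc[0] *= 10
        rho2 = sparcc_correlations(OTUTable(scaled)).to_numpy()
        np.testing.assert_allclose(rho1, rho2, atol=1e-9)

    def test_duplicated_taxon_detected_as_strong_pair(self, null_table):
        data = null_table.data.iloc[:, :10].copy()
        data["dup"] = data.iloc[:, 0]
        rho = sparcc_correlations(OTUTable(data))
        assert abs(rho.iloc[0]["dup"]) > 0.9

    def test_truth_edges_outscore_non_edges(self, default_benchmark):
        from nbbd import split_by_phenotype

        group_a, _ = split_by_phenotype(default_benchmark.table)
        rho = sparcc_correlations(group_a).abs()
        truth = default_benchmark.truth_graph_a
        on = [rho.loc[u, v] for u, v in truth.edges()]
        taxa = list(rho.index)
        off = [rho.iloc[i, j] for i in range(len(taxa)) for j in range(i + 1, len(taxa))
               if not truth.has_edge(taxa[i], taxa[j])]
        assert np.mean(on) > np.mean(off)

    def test_too_few_taxa_rejected(self):
        t = table_from({"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 3, 1]})
        with pytest.raises(ValueError, match="4 taxa"):
            sparcc_correlations(t)


class TestMB:
    def test_chain_recovered_without_transitive_edge(self):
        chain = nx.Graph([("Ta", "Tb"), ("Tb", "Tc")])
        chain.add_nodes_from([f"N{i}" for i in range(7)])
        t = sample_counts(chain, 500, depth=10_000, zero_inflation=0.0, seed=4)
        g = build_mb(t, lambda_grid=list(np.geomspace(0.01, 1.0, 20)),
                     density_target=0.06)
        assert g.has_edge("Ta", "Tb") and g.has_edge("Tb", "Tc")
        assert not g.has_edge("Ta", "Tc")

    def test_large_penalty_empties_graph(self, small_table):
        rng = np.random.default_rng(5)
        t = table_from({f"t{i}": rng.random(20) for i in range(6)})
        g = build_mb(t, lambda_grid=[1e6])
        assert g.number_of_edges() == 0

    def test_and_rule_subset_of_or_rule(self):
        rng = np.random.default_rng(6)
        t = table_from({f"t{i}": rng.integers(1, 100, 30) for i in range(8)})
        lam = [0.05]
        or_edges = set(map(frozenset, build_mb(t, lam, "OR", density_target=1.0).edges()))
        and_edges = set(map(frozenset, build_mb(t, lam, "AND", density_target=1.0).edges()))
        assert and_edges <= or_edges

    def test_empty_grid_rejected(self, small_table):
        with pytest.raises(ValueError, match="empty"):
            build_mb(small_table, lambda_grid=[])


class TestRMT:
    def test_unreachable_fixed_threshold_empties_graph(self, group_table):
        g = build_rmt(group_table, threshold_mode="fixed", fixed_threshold=1.01)
        assert g.number_of_edges() == 0

    def test_zero_threshold_gives_complete_graph(self, group_table):
        g = build_rmt(group_table, threshold_mode="fixed", fixed_threshold=0.0)
        n = g.number_of_nodes()
        assert g.number_of_edges() == n * (n - 1) / 2

    def test_auto_threshold_inside_grid_and_nonempty(self, group_table):
        g = build_rmt(group_table)
        assert 0.30 <= g.graph["threshold"] <= 0.95
        assert g.number_of_edges() > 0


class TestEdgeListIO:
    def test_round_trip_preserves_nodes_and_weights(self, tmp_path):
        g = nx.Graph()
        g.add_edge("b", "a", weight=-0.5)
        g.add_edge("c", "d", weight=0.25)
        g.add_node("isolated")
        p = tmp_path / "net.tsv"
        write_edge_list(g, p)
        back = read_edge_list(p)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges())) == set(map(frozenset, g.edges()))
        assert back["a"]["b"]["weight"] == pytest.approx(-0.5)
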