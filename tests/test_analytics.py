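import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexpanel.analytics import (
    build_topology_network,
    compute_topology_metrics,
    correlation_pvalue,
    designate_panels,
    enrich_pathways,
    export_network,
    extract_function_genes,
    landmark_genes,
    ros_production_rate,
)
from coexpanel.errors import ParameterError
from coexpanel.panels import PanelAssignment


def _annot(genes, descriptions=None, pathways=None):
    return pd.DataFrame(
        {
            "signal_peptide": [False] * len(genes),
            "transmembrane": [False] * len(genes),
            "pathways": pathways or [[] for _ in genes],
            "description": descriptions or ["" for _ in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


def _expr(genes, values, samples=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestExtractFunctionGenes:
    def test_keyword_substring_match(self):
        annot = _annot(["g1", "g2"], ["nitrate reductase alpha subunit", "kinase"])
        expr = _expr(["g1", "g2"], [[5, 5], [5, 5]])
        assert extract_function_genes(annot, ["nitrate", "nitrite"], expr) == ["g1"]

    def test_case_insensitive(self):
        annot = _annot(["g1"], ["NITRITE transporter"])
        expr = _expr(["g1"], [[2, 2]])
        assert extract_function_genes(annot, ["nitrite"], expr) == ["g1"]

    def test_low_expression_excluded(self):
        annot = _annot(["g1"], ["nitrate reductase"])
        expr = _expr(["g1"], [[0.4, 0.4]])
        assert extract_function_genes(annot, ["nitrate"], expr) == []

    def test_counts_on_planted_mixture(self):
        genes = [f"g{i}" for i in range(15)]
        desc = (
            ["nitrate reductase"] * 7
            + ["nitrite oxidoreductase"] * 4
            + ["unrelated"] * 4
        )
        vals = np.full((15, 3), 5.0)
        vals[0] = vals[7] = 0.2  # one nitrate + one nitrite gene below cutoff
        out = extract_function_genes(
            _annot(genes, desc), ["nitrate", "nitrite"], _expr(genes, vals)
        )
        assert len(out) == 9

    def test_empty_keywords_rejected(self):
        with pytest.raises(ParameterError):
            extract_function_genes(_annot(["g1"]), [], _expr(["g1"], [[1]]))


class TestEnrichPathways:
    def _panel(self, light_factor=4.0, n=10, base=10.0, pathway="P1"):
        genes = [f"g{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        dark = base * rng.uniform(0.9, 1.1, size=(n, 3))
        light = dark * light_factor * rng.uniform(0.95, 1.05, size=(n, 3))
        expr = pd.DataFrame(
            np.hstack([light, dark]),
            index=genes,
            columns=["b1", "b2", "b3", "d1", "d2", "d3"],
        )
        annot = _annot(genes, pathways=[[pathway] for _ in genes])
        return genes, annot, expr

    def test_identical_light_dark_fails_filter(self):
        genes = [f"g{i}" for i in range(5)]
        vals = np.tile(np.full((5, 3), 20.0), (1, 2))
        expr = pd.DataFrame(
            vals, index=genes, columns=["b1", "b2", "b3", "d1", "d2", "d3"]
        )
        annot = _annot(genes, pathways=[["P1"]] * 5)
        out = enrich_pathways(
            genes, annot, expr, ["b1", "b2", "b3"], ["d1", "d2", "d3"]
        )
        row = out.iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert not row["passes_filter"]

    def test_strong_upregulation_passes_all_clauses(self):
        genes, annot, expr = self._panel(light_factor=4.0, base=10.0)
        out = enrich_pathways(
            genes, annot, expr, ["b1", "b2", "b3"], ["d1", "d2", "d3"]
        )
        row = out.iloc[0]
        assert row["p_value"] < 0.01
        assert row["fold_change"] > 2.0
        assert row["mean_expression"] >= 10.0
        assert row["passes_filter"]

    def test_small_pathway_never_passes(self):
        genes, annot, expr = self._panel(n=2)
        out = enrich_pathways(
            genes, annot, expr, ["b1", "b2", "b3"], ["d1", "d2", "d3"]
        )
        assert np.isnan(out.iloc[0]["p_value"])
        assert not out.iloc[0]["passes_filter"]

    def test_member_counts_match_brute_force(self):
        genes = [f"g{i}" for i in range(12)]
        pathways = [["A"], ["A", "B"], ["B"], ["A"]] * 3
        annot = _annot(genes, pathways=pathways)
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.uniform(5, 50, size=(12, 6)),
            index=genes,
            columns=["b1", "b2", "b3", "d1", "d2", "d3"],
        )
        out = enrich_pathways(
            genes, annot, expr, ["b1", "b2", "b3"], ["d1", "d2", "d3"]
        ).set_index("pathway")
        assert out.loc["A", "n_genes"] == 9
        assert out.loc["B", "n_genes"] == 6
        # multiset conservation: counts sum to (gene, pathway) pair count
        assert out["n_genes"].sum() == sum(len(p) for p in pathways)
        # mean matches brute-force tally
        members_a = [g for g, p in zip(genes, pathways) if "A" in p]
        expected = expr.loc[members_a, ["b1", "b2", "b3"]].mean(axis=1).mean()
        assert out.loc["A", "mean_expression"] == pytest.approx(expected)


class TestDesignatePanels:
    def _setup(self):
        genes = [f"g{i}" for i in range(20)]
        labels = np.r_[np.full(10, 4), np.full(10, 2)]
        assign = PanelAssignment(genes, labels, 4, "test")
        expr = pd.DataFrame(
            np.full((20, 3), 5.0), index=genes, columns=["b1", "b2", "d1"]
        )
        return genes, assign, expr

    def test_plurality_designation(self):
        genes, assign, expr = self._setup()
        pd_genes = genes[:8] + genes[10:12]  # 80% in cluster 4
        photo = genes[12:17]  # cluster 2
        out = designate_panels(assign, pd_genes, photo, expr)
        assert out.hgp == 4
        assert out.sgp == 2
        assert not out.conflict

    def test_tie_broken_by_summed_expression(self):
        genes = [f"g{i}" for i in range(10)]
        labels = np.r_[np.full(5, 1), np.full(5, 2)]
        assign = PanelAssignment(genes, labels, 2, "test")
        vals = np.full((10, 2), 1.0)
        vals[5:] = 9.0  # cluster 2 much more expressed
        expr = pd.DataFrame(vals, index=genes, columns=["b1", "d1"])
        photo = genes[:5] + genes[5:]  # 5 vs 5 split
        with pytest.warns(UserWarning, match="tie"):
            out = designate_panels(assign, ["g0"], photo, expr)
        assert out.sgp == 2

    def test_empty_set_skips_with_warning(self):
        genes, assign, expr = self._setup()
        with pytest.warns(UserWarning, match="skipped"):
            out = designate_panels(assign, [], genes[:5], expr)
        assert out.hgp is None

    def test_matches_brute_force_plurality(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        labels = rng.integers(1, 5, size=50)
        assign = PanelAssignment(genes, labels, 4, "test")
        expr = pd.DataFrame(
            rng.uniform(1, 10, size=(50, 3)), index=genes, columns=["b1", "b2", "d1"]
        )
        chosen = rng.choice(genes, size=17, replace=False).tolist()
        counts = pd.Series([labels[genes.index(g)] for g in chosen]).value_counts()
        if (counts == counts.max()).sum() > 1:
            pytest.skip("tie; covered elsewhere")
        out = designate_panels(assign, chosen, chosen, expr)
        assert out.hgp == counts.idxmax()


class TestBuildTopologyNetwork:
    def test_duplicated_rows_give_perfect_edge(self):
        expr = _expr(["a", "b"], [[1.0, 2.0, 3.0, 4.0]] * 2)
        net = build_topology_network(expr)
        assert net.has_edge("a", "b")
        assert net["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_excluded_under_signed_rule(self):
        expr = _expr(["a", "b"], [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert not build_topology_network(expr).has_edge("a", "b")
        assert build_topology_network(expr, absolute=True).has_edge("a", "b")

    def test_zero_variance_gene_excluded(self):
        expr = _expr(["a", "b", "c"], [[1, 2, 3, 4], [1, 2, 3, 4], [5, 5, 5, 5]])
        net = build_topology_network(expr)
        assert "c" not in net.nodes

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        vals = rng.normal(size=(10, 6))
        vals[1] = vals[0] * 2 + rng.normal(0, 0.01, 6)  # plant one strong pair
        expr = _expr(genes, vals)
        net = build_topology_network(expr, r_min=0.9, p_max=0.05)
        from scipy.stats import pearsonr

        expected = set()
        for i in range(10):
            for j in range(i + 1, 10):
                r, p = pearsonr(vals[i], vals[j])
                if r >= 0.9 and p <= 0.05:
                    expected.add((genes[i], genes[j]))
        got = {tuple(sorted(e)) for e in net.edges}
        assert got == {tuple(sorted(e)) for e in expected}

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            build_topology_network(_expr(["a", "b"], [[1, 2], [3, 4]]))

    def test_pvalue_transform_matches_pearsonr(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(1)
        for m in (4, 6, 10):
            x, y = rng.normal(size=m), rng.normal(size=m)
            r, p = pearsonr(x, y)
            assert correlation_pvalue(np.array([r]), m)[0] == pytest.approx(
                p, abs=1e-9
            )


class TestTopologyMetrics:
    def test_four_cycle(self):
        net = nx.cycle_graph(4)
        nx.set_edge_attributes(net, 1.0, "weight")
        metrics = compute_topology_metrics(net)
        assert (metrics["degree"] == 2).all()
        assert (metrics["clustering_coefficient"] == 0).all()
        assert (metrics["eccentricity"] == 2).all()

    def test_triangle(self):
        net = nx.complete_graph(3)
        nx.set_edge_attributes(net, 1.0, "weight")
        metrics = compute_topology_metrics(net)
        assert (metrics["clustering_coefficient"] == 1.0).all()
        assert (metrics["betweenness"] == 0.0).all()

    def test_two_cliques_with_bridge(self):
        net = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        net.add_edge(0, 5)
        nx.set_edge_attributes(net, 1.0, "weight")
        metrics = compute_topology_metrics(net, seed=0)
        assert metrics["modularity_class"].nunique() == 2
        bridge = metrics.loc[[0, 5], "betweenness"]
        assert (bridge >= metrics.drop([0, 5])["betweenness"].max()).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_igraph_reference(self, seed):
        rng = np.random.default_rng(seed)
        A = np.triu(rng.random((15, 15)) < 0.3, k=1)
        net = nx.from_numpy_array((A + A.T).astype(int))
        if net.number_of_edges() == 0:
            pytest.skip("empty graph")
        nx.set_edge_attributes(net, 1.0, "weight")
        metrics = compute_topology_metrics(net)
        g = ig.Graph.Adjacency((A + A.T).astype(int).tolist(), mode="undirected")
        assert metrics["degree"].tolist() == g.degree()
        np.testing.assert_allclose(
            metrics["betweenness"].to_numpy(), g.betweenness(), atol=1e-9
        )
        ig_clust = np.nan_to_num(
            np.array(g.transitivity_local_undirected(mode="zero"))
        )
        np.testing.assert_allclose(
            metrics["clustering_coefficient"].to_numpy(), ig_clust, atol=1e-9
        )

    def test_disconnected_components_handled(self):
        net = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        nx.set_edge_attributes(net, 1.0, "weight")
        metrics = compute_topology_metrics(net)
        assert metrics.loc[0, "eccentricity"] == 2
        assert metrics.loc[3, "eccentricity"] == 1


class TestLandmarkGenes:
    def _metrics(self, genes, classes):
        return pd.DataFrame(
            {"modularity_class": classes}, index=pd.Index(genes, name="gene_id")
        )

    def test_small_class_returns_all(self):
        metrics = self._metrics(["a", "b"], [0, 0])
        expr = _expr(["a", "b"], [[1, 2], [3, 4]], samples=["b1", "b2"])
        out = landmark_genes(metrics, expr, ["b1", "b2"])
        assert sorted(out[0]) == ["a", "b"]

    def test_top_three_by_light_mean(self):
        genes = list("abcde")
        metrics = self._metrics(genes, [0] * 5)
        vals = np.array([[5.0], [3.0], [9.0], [1.0], [7.0]])
        expr = _expr(genes, vals, samples=["b1"])
        out = landmark_genes(metrics, expr, ["b1"])
        assert out[0] == ["c", "e", "a"]

    def test_tie_broken_lexicographically(self):
        genes = list("abcd")
        metrics = self._metrics(genes, [0] * 4)
        vals = np.array([[9.0], [5.0], [5.0], [5.0]])
        expr = _expr(genes, vals, samples=["b1"])
        out = landmark_genes(metrics, expr, ["b1"])
        assert out[0] == ["a", "b", "c"]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        metrics = self._metrics(genes, [0, 0, 0, 0, 1, 1, 1, 1])
        vals = rng.uniform(1, 100, size=(8, 3))
        expr = _expr(genes, vals, samples=["b1", "b2", "b3"])
        out1 = landmark_genes(metrics, expr, ["b1", "b2"])
        shuffled = expr.sample(frac=1, random_state=1)
        out2 = landmark_genes(metrics, shuffled, ["b1", "b2"])
        assert out1 == out2


class TestExportNetwork:
    def test_gexf_round_trip(self, tmp_path):
        net = nx.complete_graph(3)
        nx.set_edge_attributes(net, 0.95, "weight")
        metrics = compute_topology_metrics(net)
        path = tmp_path / "net.gexf"
        export_network(net, metrics, path)
        back = nx.read_gexf(path)
        assert back.number_of_nodes() == 3
        assert "betweenness" in back.nodes["0"]


class TestRosProductionRate:
    def test_no_consumption_is_zero(self):
        assert ros_production_rate(1.2, 1.2, 0.8) == 0.0

    def test_forced_arithmetic(self):
        assert ros_production_rate(0.6, 1.2, 0.5) == pytest.approx(1000.0)

    def test_vectorized_equals_scalar_loop(self):
        a_t = np.array([1.1, 1.0, 0.95, 0.9])
        out = ros_production_rate(a_t, 1.2, 0.5)
        for k, at in zip(out, a_t):
            assert k == pytest.approx(ros_production_rate(float(at), 1.2, 0.5))

    def test_depleted_substrate_warns(self):
        with pytest.warns(UserWarning, match="substrate"):
            ros_production_rate(0.5, 1.2, 0.5)

    def test_bad_od(self):
        with pytest.raises(ParameterError):
            ros_production_rate(1.0, 1.2, 0.0)
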