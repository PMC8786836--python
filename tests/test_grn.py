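"""Aggregation, co-accessibility, base-GRN assembly, ridge fitting, stats."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scregnet import grn, simulate


class TestSampleAggregates:
    def test_k1_yields_distinct_singletons(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(50, 3))
        cfg = grn.CoaccessConfig(k=1, n_iterations=100, overlap_cutoff=0.99)
        aggs = grn.sample_aggregates(coords, cfg, seed=1)
        flat = [int(a[0]) for a in aggs]
        assert len(flat) == len(set(flat))

    def test_duplicate_candidate_rejected(self):
        coords = np.zeros((30, 2))  # all identical -> identical neighbor sets
        cfg = grn.CoaccessConfig(k=10, n_iterations=50, overlap_cutoff=0.8)
        aggs = grn.sample_aggregates(coords, cfg, seed=0)
        assert len(aggs) == 1

    def test_overlap_constraint_and_determinism(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(600, 4))
        cfg = grn.CoaccessConfig(k=40, n_iterations=200, overlap_cutoff=0.8)
        a = grn.sample_aggregates(coords, cfg, seed=7)
        b = grn.sample_aggregates(coords, cfg, seed=7)
        assert len(a) == len(b) and all(np.array_equal(x, y) for x, y in zip(a, b))
        assert len(a) < 200
        for s1, s2 in itertools.combinations(a, 2):
            assert len(set(s1) & set(s2)) / cfg.k <= cfg.overlap_cutoff

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError, match="at least"):
            grn.sample_aggregates(np.zeros((5, 2)), grn.CoaccessConfig(k=10), seed=0)


def _peak_table(n, spacing=10_000, chrom="chr1"):
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + 501,
         "name": [f"p{i}" for i in range(n)]}
    )


class TestCoaccessibility:
    def test_identical_peaks_fully_correlated(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(300, 4)).astype(float)
        counts[:, 1] = counts[:, 0]  # identical signal
        aggs = [np.array([i, i + 1, i + 2]) for i in range(0, 297, 3)]
        cfg = grn.CoaccessConfig(k=3, fdr_max=1e-3, corr_min=0.5, variability_min=0.0)
        tab = grn.compute_coaccessibility(counts, aggs, _peak_table(4), cfg)
        pairs = set(map(tuple, tab[["peak1", "peak2"]].to_numpy()))
        assert ("p0", "p1") in pairs and ("p1", "p0") in pairs

    def test_cross_chromosome_pairs_never_tested(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(90, 2)).astype(float)
        counts[:, 1] = counts[:, 0]
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [501, 501],
             "name": ["a", "b"]}
        )
        aggs = [np.array([i, i + 1]) for i in range(0, 88, 2)]
        cfg = grn.CoaccessConfig(k=2, fdr_max=0.5, corr_min=0.0, variability_min=0.0)
        tab = grn.compute_coaccessibility(counts, aggs, peaks, cfg)
        assert len(tab) == 0

    def test_distance_window_respected(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5.0, size=(90, 2)).astype(float)
        counts[:, 1] = counts[:, 0]
        peaks = _peak_table(2, spacing=400_000)
        aggs = [np.array([i, i + 1]) for i in range(0, 88, 2)]
        cfg = grn.CoaccessConfig(k=2, fdr_max=0.5, corr_min=0.0, variability_min=0.0)
        assert len(grn.compute_coaccessibility(counts, aggs, peaks, cfg)) == 0

    def test_independent_noise_rarely_exceeds_correlation_cutoff(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(600, 40)).astype(float)
        aggs = [np.arange(i, i + 3) for i in range(0, 597, 3)]
        cfg = grn.CoaccessConfig(
            k=3, fdr_max=1.1, corr_min=-1.1, variability_min=0.0,
            max_distance=10_000_000,
        )
        tab = grn.compute_coaccessibility(counts, aggs, _peak_table(40), cfg)
        assert (tab.correlation.abs() < 0.5).mean() >= 0.99

    def test_table_symmetric_and_bh_monotone(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(4.0, size=(300, 6)).astype(float)
        counts[:, 1] = counts[:, 0] + rng.poisson(1.0, 300)
        aggs = [np.arange(i, i + 3) for i in range(0, 297, 3)]
        cfg = grn.CoaccessConfig(
            k=3, fdr_max=1.1, corr_min=-1.1, variability_min=0.0
        )
        tab = grn.compute_coaccessibility(counts, aggs, _peak_table(6), cfg)
        forward = tab.set_index(["peak1", "peak2"]).correlation
        for (a, b), r in forward.items():
            assert forward[(b, a)] == r
        half = tab[tab.peak1 < tab.peak2].sort_values("p_value")
        assert (half.fdr.diff().dropna() >= -1e-12).all()

    def test_too_few_aggregates_raise(self):
        with pytest.raises(ValueError, match="aggregates"):
            grn.compute_coaccessibility(
                np.ones((10, 2)), [np.array([0])], _peak_table(2), grn.CoaccessConfig(k=1)
            )


class TestBaseGrn:
    PEAKS = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [100, 5_000, 9_000, 20_000, 40_000],
            "end": [601, 5_501, 9_501, 20_501, 40_501],
            "name": [f"p{i}" for i in range(5)],
        }
    )
    TSS = pd.DataFrame(
        {"gene": ["gA", "gB", "gC"], "chrom": ["chr1"] * 3, "tss": [300, 5_200, 33_000],
         "strand": ["+", "+", "-"]}
    )

    def _hits(self, mapping):
        hits = pd.DataFrame(
            False, index=self.PEAKS.name, columns=["m1", "m2"]
        )
        for pk, m in mapping:
            hits.at[pk, m] = True
        return hits

    def test_tss_peak_motif_gives_candidate(self):
        hits = self._hits([("p0", "m1")])
        base = grn.assemble_base_grn(
            pd.DataFrame(columns=["peak1", "peak2", "correlation"]),
            self.PEAKS, self.TSS, hits, {"m1": ["TF1"]},
        )
        assert base.candidates["gA"] == {"TF1"}

    def test_coaccessibility_threshold_rule(self):
        hits = self._hits([("p3", "m2")])
        for r, linked in [(0.6, True), (0.4, False)]:
            co = pd.DataFrame(
                {"peak1": ["p0"], "peak2": ["p3"], "correlation": [r]}
            )
            base = grn.assemble_base_grn(
                co, self.PEAKS, self.TSS, hits, {"m2": ["TF2"]}
            )
            assert ("TF2" in base.candidates["gA"]) == linked

    def test_hand_drawn_toy_enumeration(self):
        # gA: TSS peak p0 (m1->TF1) + coaccessible p3 (m2->TF2)
        # gB: TSS peak p1, no motifs -> empty
        # gC: no TSS peak -> counted, empty
        hits = self._hits([("p0", "m1"), ("p3", "m2")])
        co = pd.DataFrame({"peak1": ["p0"], "peak2": ["p3"], "correlation": [0.7]})
        base = grn.assemble_base_grn(
            co, self.PEAKS, self.TSS, hits, {"m1": ["TF1"], "m2": ["TF2"]}
        )
        assert base.candidates == {"gA": {"TF1", "TF2"}, "gB": set(), "gC": set()}
        assert base.genes_without_tss_peak == ["gC"]


class TestFitClusterGrn:
    def test_independent_noise_target_fully_pruned(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(500, 6)), columns=list("abcdef"))
        fits = grn.fit_cluster_grn(df, np.zeros(500, int), {"f": set("abcde")}, seed=1)
        edges = fits["0"].edges
        assert edges.retained.sum() == 0
        assert (edges.p_value > 0.001).all() or (edges.weight.abs() < 0.05).all()

    def test_single_regulator_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=0)  # sum of squares exactly 100
        y = 2.0 * x
        cfg = grn.GrnFitConfig(alpha=10.0, n_bags=1, bootstrap=False)
        fits = grn.fit_cluster_grn(
            pd.DataFrame({"r": x, "t": y}), np.zeros(100, int), {"t": {"r"}}, cfg
        )
        w = fits["0"].edges.weight.iloc[0]
        assert w == pytest.approx(200.0 / 110.0, abs=1e-8)

    def test_matches_closed_form_ridge_multivariate(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(0, 0.1, 80)
        df = pd.DataFrame(np.column_stack([X, y]), columns=["a", "b", "c", "t"])
        cfg = grn.GrnFitConfig(alpha=10.0, n_bags=1, bootstrap=False)
        fits = grn.fit_cluster_grn(df, np.zeros(80, int), {"t": {"a", "b", "c"}}, cfg)
        edges = fits["0"].edges.set_index("regulator").weight
        Xc = X - X.mean(0)
        yc = y - y.mean()
        oracle = np.linalg.solve(Xc.T @ Xc + 10.0 * np.eye(3), Xc.T @ yc)
        for name, w in zip(["a", "b", "c"], oracle):
            assert edges[name] == pytest.approx(w, abs=1e-8)

    def test_marker_restriction_prunes_nonmarkers(self, truth_grn, grn_expression):
        base = {g: set(truth_grn.genes[:5]) for g in truth_grn.genes[5:]}
        markers = {"0": {truth_grn.genes[0]}}
        fits = grn.fit_cluster_grn(
            grn_expression, np.zeros(len(grn_expression), int), base,
            marker_genes=markers, seed=0,
        )
        retained = fits["0"].retained_edges()
        assert set(retained.regulator) <= {truth_grn.genes[0]}

    def test_pruning_monotone_in_thresholds(self, truth_grn, grn_expression):
        base = {g: set(truth_grn.genes[:5]) for g in truth_grn.genes[5:]}
        loose = grn.GrnFitConfig(prune_p=0.05, prune_w=0.001)
        tight = grn.GrnFitConfig(prune_p=0.001, prune_w=0.01)
        labels = np.zeros(len(grn_expression), int)
        e_loose = grn.fit_cluster_grn(grn_expression, labels, base, loose, seed=4)["0"]
        e_tight = grn.fit_cluster_grn(grn_expression, labels, base, tight, seed=4)["0"]
        loose_set = set(map(tuple, e_loose.retained_edges()[["regulator", "target"]].to_numpy()))
        tight_set = set(map(tuple, e_tight.retained_edges()[["regulator", "target"]].to_numpy()))
        assert tight_set <= loose_set


def _brute_force_betweenness(G):
    """Count, for every ordered pair (s, t), the fraction of shortest paths
    through each intermediate node, by exhaustive path enumeration."""
    nodes = list(G.nodes)
    btw = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(G, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                btw[v] += through / len(paths)
    return btw


class TestNetworkStats:
    def test_chain_betweenness(self):
        edges = pd.DataFrame({"regulator": ["A", "B"], "target": ["B", "C"]})
        stats = grn.network_stats(edges).set_index("node")
        assert stats.betweenness["B"] == 1.0
        assert stats.betweenness["A"] == 0.0 and stats.betweenness["C"] == 0.0

    def test_star_outdegree(self):
        edges = pd.DataFrame(
            {"regulator": ["H"] * 5, "target": [f"t{i}" for i in range(5)]}
        )
        stats = grn.network_stats(edges).set_index("node")
        assert stats.outdegree["H"] == 5

    def test_random_digraphs_match_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            G = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1e6)), directed=True)
            edges = pd.DataFrame(
                [(f"n{u}", f"n{v}") for u, v in G.edges], columns=["regulator", "target"]
            )
            if edges.empty:
                continue
            stats = grn.network_stats(edges).set_index("node")
            H = nx.DiGraph([(f"n{u}", f"n{v}") for u, v in G.edges])
            oracle = _brute_force_betweenness(H)
            for v, b in oracle.items():
                assert stats.betweenness[v] == pytest.approx(b, abs=1e-9)

    def test_specificity_ratio(self):
        edges = pd.DataFrame({"regulator": ["A"], "target": ["B"]})
        expr = pd.DataFrame({"A": [1.0, 2.0, 4.0], "B": [1.0, 1.0, 1.0]})
        stats = grn.network_stats(
            edges, expr, np.array(["c1", "c2", "c3"])
        ).set_index("node")
        # cluster means (1, 2, 4), median 2 -> specificity (0.5, 1, 2)
        assert stats.loc["A", "specificity_c3"] == pytest.approx(2.0)

    def test_empty_network(self):
        out = grn.network_stats(pd.DataFrame(columns=["regulator", "target"]))
        assert out.empty


class TestRankRegulators:
    EDGES = pd.DataFrame(
        {
            "regulator": ["r1"] * 5 + ["r2"] * 3 + ["r3"] * 2 + ["r4"],
            "target": [f"f{i}" for i in range(5)]
            + ["f0", "f1", "x0"]
            + ["f0", "x1"]
            + ["x2"],
            "weight": [0.5] * 11,
        }
    )
    FOCUS = {f"f{i}" for i in range(5)}

    def test_intersection_ordering(self):
        rr = grn.rank_regulators(self.EDGES, self.FOCUS, top_n=4)
        assert rr.ranking.regulator.tolist() == ["r1", "r2", "r3", "r4"]
        assert rr.ranking.n_focus_targets.tolist() == [5, 2, 1, 0]

    def test_weight_cutoff_drops_edges(self):
        edges = self.EDGES.copy()
        edges.loc[edges.regulator == "r1", "weight"] = 0.005
        rr = grn.rank_regulators(edges, self.FOCUS, top_n=4)
        assert rr.ranking.regulator.iloc[0] == "r2"
        assert "r1" not in set(rr.ranking.regulator)

    def test_zero_activity_for_silent_cluster(self):
        expr = pd.DataFrame(
            {r: [0.0, 1.0] for r in ["r1", "r2", "r3", "r4"]}
        )
        rr = grn.rank_regulators(
            self.EDGES, self.FOCUS, top_n=4,
            partitioner=lambda G, resolution, seed: {v: 0 for v in G.nodes},
            expression=expr, clusters=np.array(["silent", "active"]),
        )
        assert rr.activity.loc["silent", "community_0"] == 0.0

    def test_empty_focus_raises(self):
        with pytest.raises(ValueError):
            grn.rank_regulators(self.EDGES, set())
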