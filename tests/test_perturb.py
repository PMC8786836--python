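"""Knockout propagation, projection, abundance CIs, staging."""

import numpy as np
import pandas as pd
import pytest

from scregnet import perturb, simulate


CHAIN = pd.DataFrame(
    {"regulator": ["A", "B"], "target": ["B", "C"], "weight": [0.5, 0.5]}
)
BASE3 = pd.DataFrame([[1.0, 1.0, 1.0]], columns=["A", "B", "C"])


class TestSimulateKo:
    def test_no_outgoing_edges_leaves_others_untouched(self):
        edges = pd.DataFrame({"regulator": ["B"], "target": ["C"], "weight": [0.5]})
        delta = perturb.simulate_ko(edges, BASE3, perturb.KoConfig(ko_genes=("A",)))
        assert delta.values.tolist() == [[-1.0, 0.0, 0.0]]

    @pytest.mark.parametrize("depth", [2, 3, 5])
    def test_chain_propagation(self, depth):
        delta = perturb.simulate_ko(
            CHAIN, BASE3, perturb.KoConfig(ko_genes=("A",), depth=depth)
        )
        assert np.allclose(delta.values, [[-1.0, -0.5, -0.25]])

    def test_two_cycle_matches_truncated_series_oracle(self):
        edges = pd.DataFrame(
            {"regulator": ["A", "B"], "target": ["B", "A"], "weight": [0.5, 0.5]}
        )
        base = pd.DataFrame([[2.0, 3.0]], columns=["A", "B"])
        depth = 5
        delta = perturb.simulate_ko(
            edges, base, perturb.KoConfig(ko_genes=("A",), depth=depth, clipping="none")
        )
        # oracle: truncated geometric series on the free subsystem
        # free gene B receives W[A->B] * (-baseline_A) each step; the free-free
        # block is empty here so the series stops after one term
        assert delta.values[0].tolist() == [-2.0, 0.5 * -2.0]

    def test_depth_matches_series_and_converges_to_fixed_point(self, truth_grn):
        baseline = pd.DataFrame(
            [truth_grn.baseline], columns=truth_grn.genes
        )
        ko = (truth_grn.genes[0],)
        # independent oracle: explicit truncated matrix-power sum on the
        # reduced system delta_f(d) = sum_{t<d} (A^T)^t b
        W = truth_grn.weight_matrix()
        idx = {g: i for i, g in enumerate(truth_grn.genes)}
        ko_i = [idx[ko[0]]]
        free = [i for i in range(len(truth_grn.genes)) if i not in ko_i]
        A = W.T[np.ix_(free, free)]
        b = W.T[np.ix_(free, ko_i)] @ (-baseline.values[:, ko_i].T)
        for depth in (1, 3, 5):
            series = np.zeros_like(b)
            term = b.copy()
            for _ in range(depth):
                series += term
                term = A @ term
            delta = perturb.simulate_ko(
                truth_grn.edges, baseline,
                perturb.KoConfig(ko_genes=ko, depth=depth, clipping="none"),
            )
            assert np.allclose(delta.values[0][free], series.ravel(), atol=1e-12)
        deep = perturb.simulate_ko(
            truth_grn.edges, baseline,
            perturb.KoConfig(ko_genes=ko, depth=200, clipping="none"),
        )
        fp = perturb.ko_fixed_point(truth_grn.edges, baseline, ko)
        assert np.allclose(deep.values, fp.values, atol=1e-10)

    def test_absent_ko_gene_warns_with_zero_delta(self):
        with pytest.warns(UserWarning, match="absent"):
            delta = perturb.simulate_ko(
                CHAIN, BASE3, perturb.KoConfig(ko_genes=("Z",))
            )
        assert (delta.values == 0).all()

    def test_nonneg_clipping_floors_expression(self):
        edges = pd.DataFrame(
            {"regulator": ["A"], "target": ["B"], "weight": [5.0]}
        )
        base = pd.DataFrame([[1.0, 2.0]], columns=["A", "B"])
        delta = perturb.simulate_ko(
            edges, base, perturb.KoConfig(ko_genes=("A",), depth=1, clipping="nonneg")
        )
        assert (base.values + delta.values >= 0).all()


class TestCompareSimVsExp:
    def test_identical_vectors(self):
        v = pd.Series([1.0, 3.0, 2.0, 5.0], index=list("abcd"))
        rho, _, _ = perturb.compare_sim_vs_exp(v, v)
        assert rho == pytest.approx(1.0)

    def test_rank_reversal(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        rho, _, _ = perturb.compare_sim_vs_exp(v, -v)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        v = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            perturb.compare_sim_vs_exp(v, pd.Series([1.0, 1.0, 1.0], index=list("abc")))

    def test_synthetic_ko_self_consistency(self):
        truth = simulate.random_grn(
            n_genes=400, n_regulators=6, targets_per_regulator=80,
            noise_sd=0.5, seed=5,
        )
        ko = (truth.genes[0],)
        wt = simulate.simulate_grn_expression(truth, 400, seed=1)
        ex = simulate.simulate_ko_expression(truth, ko, 400, seed=2)
        wt_mean = pd.Series(np.asarray(wt.X).mean(0), index=wt.var_names)
        ko_mean = pd.Series(np.asarray(ex.X).mean(0), index=ex.var_names)
        log2fc = np.log2(np.clip(ko_mean, 0, None) + 1) - np.log2(
            np.clip(wt_mean, 0, None) + 1
        )
        baseline = pd.DataFrame([truth.baseline], columns=truth.genes)
        delta = perturb.simulate_ko(
            truth.edges, baseline, perturb.KoConfig(ko_genes=ko, depth=5)
        )
        net = sorted(set(truth.edges.regulator) | set(truth.edges.target))
        rho, _, _ = perturb.compare_sim_vs_exp(delta.iloc[0][net], log2fc[net])
        assert rho > 0.6


class TestClassifyKnn:
    def test_exact_atlas_cell_with_k1(self):
        atlas = np.array([[0.0, 0.0], [5.0, 5.0]])
        res = perturb.classify_knn(atlas[:1], atlas, ["x", "y"], k=1)
        assert res.labels.iloc[0] == "x"
        assert res.probabilities.iloc[0]["x"] == 1.0

    def test_vote_fractions(self):
        rng = np.random.default_rng(0)
        atlas = rng.normal(size=(50, 2)) * 0.01
        labels = ["X"] * 30 + ["Y"] * 20
        res = perturb.classify_knn(np.zeros((1, 2)), atlas, labels, k=50)
        assert res.probabilities.iloc[0]["X"] == pytest.approx(0.6)
        assert res.labels.iloc[0] == "X"

    def test_probabilities_sum_to_one_and_embedding_averaged(self):
        rng = np.random.default_rng(1)
        atlas = rng.normal(size=(100, 3))
        emb = rng.normal(size=(100, 2))
        res = perturb.classify_knn(
            rng.normal(size=(20, 3)), atlas, ["a"] * 50 + ["b"] * 50,
            atlas_embedding=emb, k=10,
        )
        assert np.allclose(res.probabilities.sum(axis=1), 1.0)
        assert res.embedding.shape == (20, 2)

    def test_holdout_accuracy_on_separated_clusters(self):
        rng = np.random.default_rng(2)
        atlas = np.vstack([rng.normal(0, 1, (300, 5)), rng.normal(8, 1, (300, 5))])
        labels = np.array(["A"] * 300 + ["B"] * 300)
        query = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(8, 1, (100, 5))])
        truth = np.array(["A"] * 100 + ["B"] * 100)
        res = perturb.classify_knn(query, atlas, labels, k=50)
        assert (res.labels.to_numpy() == truth).mean() > 0.95

    def test_k_larger_than_atlas_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            perturb.classify_knn(np.zeros((1, 2)), np.zeros((5, 2)), ["a"] * 5, k=6)


class TestAbundanceCi:
    def test_equal_composition_covers_zero(self):
        prob = pd.DataFrame({"c1": np.full(300, 1.0)})
        geno = pd.Series(["ctrl"] * 200 + ["ko"] * 100)
        rep = pd.Series(["r1"] * 100 + ["r2"] * 100 + ["r3"] * 50 + ["r4"] * 50)
        est = perturb.abundance_ci(prob, geno, rep, k=50, force_phi=1.0).table
        assert est.log_fc.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert est.ci_lower.iloc[0] <= 0 <= est.ci_upper.iloc[0]

    def test_two_group_closed_form(self):
        # counts (100, 100) control vs (50, 50) KO with equal offsets:
        # the genotype effect is exactly log(0.5)
        design = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        est, se, phi = perturb.fit_quasipoisson(
            np.array([100, 100, 50, 50]), design, np.zeros(4), force_phi=1.0
        )
        assert est == pytest.approx(np.log(0.5), abs=1e-8)

    def test_dispersion_forced_to_one_matches_plain_poisson(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=8)
        design = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        est1, se1, phi1 = perturb.fit_quasipoisson(y, design, np.zeros(8), force_phi=1.0)
        est2, se2, phi2 = perturb.fit_quasipoisson(y, design, np.zeros(8))
        assert est1 == pytest.approx(est2, abs=1e-10)
        assert phi1 == 1.0
        assert se2 == pytest.approx(se1 * np.sqrt(phi2), rel=1e-6)

    def test_zero_count_genotype_flagged_not_infinite(self):
        prob = pd.DataFrame({"c1": [1.0] * 100 + [0.0] * 100})
        geno = pd.Series(["ctrl"] * 100 + ["ko"] * 100)
        rep = pd.Series(["r1"] * 50 + ["r2"] * 50 + ["r3"] * 50 + ["r4"] * 50)
        est = perturb.abundance_ci(prob, geno, rep, k=50).table
        assert est.flagged.iloc[0]
        assert np.isnan(est.log_fc.iloc[0])

    def test_null_coverage_in_band(self):
        cov = perturb.null_coverage_simulation(n_sims=200, seed=3)
        assert 0.85 <= cov <= 1.0  # quick sanity; tighter band in acceptance


class TestThymusFilter:
    def _result(self, probs):
        pr = pd.DataFrame(probs, columns=["c4", "c25", "c9", "other"])
        return perturb.ProjectionResult(
            labels=pd.Series(["c4"] * len(pr)), probabilities=pr, embedding=None, k=50
        )

    def test_boundary_inclusive_and_sentinel_required(self):
        res = self._result(
            [[0.5, 0.2, 0.2, 0.1], [0.5, 0.19, 0.1, 0.21], [0.5, 0.3, 0.1, 0.1]]
        )
        expr = pd.DataFrame({"Il7": [1.0, 5.0, 0.0]}, index=res.probabilities.index)
        kept = perturb.thymus_filter(res, expr, {"c4", "c25", "c9"})
        # cell 0: score 0.9 & Il7 > 0 -> kept; cell 1: score 0.79 -> dropped;
        # cell 2: score 0.9 but Il7 == 0 -> dropped
        assert list(kept) == [0]

    def test_exact_threshold_retained(self):
        res = self._result([[0.4, 0.2, 0.2, 0.2]])
        expr = pd.DataFrame({"Il7": [2.0]})
        assert len(perturb.thymus_filter(res, expr, {"c4", "c25", "c9"})) == 1

    def test_missing_sentinel_raises(self):
        res = self._result([[1.0, 0.0, 0.0, 0.0]])
        with pytest.raises(KeyError, match="Il7"):
            perturb.thymus_filter(res, pd.DataFrame({"Gapdh": [1.0]}), {"c4"})


class TestPseudotime:
    def test_even_split(self):
        sizes = np.bincount(perturb.bin_pseudotime(np.arange(100), 20))
        assert (sizes == 5).all()

    def test_remainder_distribution(self):
        sizes = sorted(np.bincount(perturb.bin_pseudotime(np.arange(101), 20)))
        assert sizes == [5] * 19 + [6]

    def test_bins_monotone_in_pseudotime(self):
        rng = np.random.default_rng(0)
        t = rng.random(173)
        bins = perturb.bin_pseudotime(t, 20)
        order = np.argsort(t, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()

    def test_too_many_bins_raise(self):
        with pytest.raises(ValueError):
            perturb.bin_pseudotime(np.arange(5), 10)


class TestDynamicGenes:
    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, size=(200, 3)).astype(float)
        X[:, 0] = 7.0
        out = perturb.dynamic_genes(X, np.arange(200), ["const", "g1", "g2"], n_periods=10)
        row = out.set_index("gene").loc["const"]
        assert row.q_value == 1.0 and not row.selected

    def test_step_gene_detected(self):
        rng = np.random.default_rng(1)
        t = np.arange(400)
        X = rng.poisson(5.0, size=(400, 5)).astype(float)
        X[200:, 0] = rng.poisson(12.0, size=200)  # > 2x step mid-course
        out = perturb.dynamic_genes(X, t, [f"g{i}" for i in range(5)], n_periods=20)
        assert out.set_index("gene").loc["g0"].selected

    def test_permuted_pseudotime_controls_false_positives(self):
        adata = simulate.simulate_trajectory(n_cells=400, n_genes=300, n_dynamic=0, seed=2)
        rng = np.random.default_rng(3)
        t = rng.permutation(adata.obs.pseudotime.to_numpy())
        out = perturb.dynamic_genes(
            np.asarray(adata.X, float), t, list(adata.var_names), n_periods=20
        )
        assert out.selected.mean() <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 300)


@pytest.fixture(scope="module")
def trajectory():
    adata = simulate.simulate_trajectory(n_cells=800, n_genes=120, n_dynamic=24, seed=4)
    X = np.asarray(adata.X, float)
    t = adata.obs.pseudotime.to_numpy()
    bins = perturb.bin_pseudotime(t, 20)
    bulk = pd.DataFrame(
        np.vstack([X[bins == b].sum(0) for b in range(20)]),
        index=[f"bin_{b}" for b in range(20)],
        columns=adata.var_names,
    )
    dyn = perturb.dynamic_genes(X, t, list(adata.var_names), n_periods=20)
    return X, bins, bulk, sorted(dyn[dyn.selected].gene)


class TestStaging:

    def test_bin_profile_stages_to_itself(self, trajectory):
        _, _, bulk, dyn = trajectory
        stage = perturb.stage_correlate(bulk, bulk, dyn)
        for b in range(20):
            assert stage.top_bins[f"bin_{b}"][0] == f"bin_{b}"
            assert stage.correlations.loc[f"bin_{b}", f"bin_{b}"] == pytest.approx(1.0)

    def test_query_from_late_bins_recovers_neighborhood(self, trajectory):
        X, bins, bulk, dyn = trajectory
        q = pd.DataFrame(
            [X[(bins == 9) | (bins == 10)].sum(0)], index=["geno"], columns=bulk.columns
        )
        stage = perturb.stage_correlate(q, bulk, dyn)
        assert set(stage.top_bins["geno"]) <= {"bin_8", "bin_9", "bin_10", "bin_11"}

    def test_rank_correlation_invariant_to_monotone_transform(self, trajectory):
        _, _, bulk, dyn = trajectory
        q = bulk.iloc[[7]].rename(index={"bin_7": "geno"})
        a = perturb.stage_correlate(q, bulk, dyn).correlations
        b = perturb.stage_correlate(np.exp(q / q.max().max() * 3), bulk, dyn).correlations
        assert np.allclose(a.values, b.values)

    def test_too_few_bins_raise(self, trajectory):
        _, _, bulk, dyn = trajectory
        with pytest.raises(ValueError):
            perturb.stage_correlate(bulk.iloc[:1], bulk.iloc[:1], dyn)
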