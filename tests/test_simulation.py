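import numpy as np
import pandas as pd
import pytest

from lemur.simulate import (
    SimConfig,
    SimTruth,
    _gamma_poisson,
    adjusted_rand_index,
    fdp_tpr_gene_level,
    knn_mixing,
    label_cell_groups,
    make_toy_two_gene,
    prediction_l2_metrics,
    simulate_benchmark_counts,
)


class TestGammaPoissonMoments:
    def test_unit_mean_at_zero_log_mean(self):
        rng = np.random.default_rng(0)
        draws = _gamma_poisson(rng, np.ones(100_000), 0.2)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_variance_follows_mean_plus_alpha_mean_squared(self):
        rng = np.random.default_rng(1)
        mu, alpha = 4.0, 0.2
        draws = _gamma_poisson(rng, np.full(100_000, mu), alpha)
        expected_var = mu + alpha * mu**2  # 7.2
        # variance of the sample variance ~ (m4 - var^2)/n
        m4 = np.mean((draws - draws.mean()) ** 4)
        se = np.sqrt((m4 - expected_var**2) / draws.size)
        assert abs(draws.var() - expected_var) < 3 * se


class TestBenchmarkSimulator:
    def test_shapes_and_design(self):
        cfg = SimConfig(n_genes_null=50, n_genes_de=10, cells_per_sample=20, seed=0)
        ds, design, truth = simulate_benchmark_counts(cfg)
        assert ds.counts.shape == (60, 120)
        assert design.matrix.shape == (120, 2)
        assert set(np.unique(design.matrix[:, 1])) == {0.0, 1.0}
        assert truth.table["is_de"].sum() == 10

    def test_de_gene_doubles_mean_in_affected_treated_cells(self):
        cfg = SimConfig(
            n_genes_null=2,
            n_genes_de=60,
            cells_per_sample=800,
            sample_effect_sd=0.0,
            backbone_loading_sd=0.0,
            size_factor_sdlog=0.0,
            cluster_counts=(2,),
            lfc_levels=(1.0,),
            seed=1,
        )
        ds, design, truth = simulate_benchmark_counts(cfg)
        treated = design.matrix[:, 1] > 0
        ratios = []
        for _, row in truth.table[truth.table.is_de].iterrows():
            gi = int(np.flatnonzero(ds.gene_ids == row.gene)[0])
            aff = np.zeros(ds.n_cells, dtype=bool)
            aff[truth.affected_cells[row.gene]] = True
            in_mean = ds.counts[gi][aff & treated].mean()
            out_mean = ds.counts[gi][~aff & treated].mean()
            ratios.append(in_mean / out_mean)
        assert abs(np.mean(ratios) - 2.0) < 0.1

    def test_null_genes_carry_no_condition_effect(self):
        cfg = SimConfig(n_genes_null=300, n_genes_de=0, cells_per_sample=400,
                        sample_effect_sd=0.0, seed=2)
        ds, design, truth = simulate_benchmark_counts(cfg)
        treated = design.matrix[:, 1] > 0
        lfc = np.log2(
            (ds.counts[:, treated].mean(axis=1) + 0.5)
            / (ds.counts[:, ~treated].mean(axis=1) + 0.5)
        )
        assert np.abs(lfc).mean() < 0.1

    def test_affected_cells_form_one_cluster(self):
        cfg = SimConfig(n_genes_null=10, n_genes_de=20, cells_per_sample=50, seed=3)
        ds, design, truth = simulate_benchmark_counts(cfg)
        for _, row in truth.table[truth.table.is_de].iterrows():
            assert row.k_clusters in cfg.cluster_counts
            assert 0 <= row.cluster_id < row.k_clusters
            assert len(truth.affected_cells[row.gene]) > 0

    def test_smaller_clusters_receive_larger_effects(self):
        cfg = SimConfig(n_genes_null=10, n_genes_de=100, cells_per_sample=100, seed=4)
        _, _, truth = simulate_benchmark_counts(cfg)
        de = truth.table[truth.table.is_de]
        pairing = dict(zip(cfg.cluster_counts, cfg.lfc_levels))
        assert all(pairing[k] == l for k, l in zip(de.k_clusters, de.lfc))

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_genes_null=30, n_genes_de=5, cells_per_sample=10, seed=9)
        a = simulate_benchmark_counts(cfg)[0].counts
        b = simulate_benchmark_counts(cfg)[0].counts
        assert np.array_equal(a, b)


class TestToyTwoGene:
    def test_reproducible(self):
        a = make_toy_two_gene(100, 1)[0].values
        b = make_toy_two_gene(100, 1)[0].values
        assert np.array_equal(a, b)

    def test_groups_and_conditions_present(self):
        _, _, labels = make_toy_two_gene(100, 0)
        assert set(labels["group"]) == {"left", "right"}
        assert set(labels["condition"]) == {"control", "treatment"}

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            make_toy_two_gene(5, 0)


class TestKnnMixing:
    def test_separated_conditions_score_k(self):
        rng = np.random.default_rng(0)
        z = np.concatenate([rng.normal(0, 0.1, (50, 3)), rng.normal(100, 0.1, (50, 3))])
        labels = np.repeat(["a", "b"], 50)
        assert knn_mixing(z, labels, k=20) == pytest.approx(20.0)

    def test_single_condition_scores_k(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((60, 4))
        assert knn_mixing(z, np.repeat("a", 60), k=20) == pytest.approx(20.0)

    def test_balanced_identical_distributions_score_half_k(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((2000, 10))
            labels = np.tile(["a", "b"], 1000)
            vals.append(knn_mixing(z, labels, k=20))
        assert abs(np.mean(vals) - 10.0) < 0.5

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((300, 5))
        labels = rng.integers(0, 2, 300)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert knn_mixing(z, labels, k=15) == pytest.approx(
            knn_mixing(z @ q, labels, k=15)
        )

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            knn_mixing(np.zeros((10, 2)), np.zeros(10), k=10)


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 3, 3]) == pytest.approx(1.0)

    def test_printed_toy_matches_contingency_formula(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        # brute-force contingency-table evaluation
        from math import comb

        n = len(a)
        cont = pd.crosstab(a, b).to_numpy()
        sum_ij = sum(comb(int(x), 2) for x in cont.ravel())
        sum_a = sum(comb(int(x), 2) for x in cont.sum(axis=1))
        sum_b = sum(comb(int(x), 2) for x in cont.sum(axis=0))
        expected = sum_a * sum_b / comb(n, 2)
        max_idx = 0.5 * (sum_a + sum_b)
        oracle = (sum_ij - expected) / (max_idx - expected)
        assert adjusted_rand_index(a, b) == pytest.approx(oracle)

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, 2000)
        b = rng.integers(0, 5, 2000)
        assert abs(adjusted_rand_index(a, b)) < 0.05

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])


class TestFdpTpr:
    def make_truth(self, is_de):
        return SimTruth(
            table=pd.DataFrame(
                {"gene": [f"g{i}" for i in range(len(is_de))], "is_de": is_de,
                 "lfc": 0.0, "k_clusters": 0, "cluster_id": -1}
            )
        )

    def table(self, adj_p):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(adj_p))], "adj_p_value": adj_p}
        )

    def test_no_calls(self):
        truth = self.make_truth([True, False])
        fdp, tpr = fdp_tpr_gene_level(self.table([0.5, 0.5]), truth, 0.1)
        assert (fdp, tpr) == (0.0, 0.0)

    def test_perfect_calls(self):
        truth = self.make_truth([True, True, False])
        fdp, tpr = fdp_tpr_gene_level(self.table([0.01, 0.01, 0.9]), truth, 0.1)
        assert (fdp, tpr) == (0.0, 1.0)

    def test_mixed_counts(self):
        is_de = [True] * 20 + [False] * 30
        adj = np.ones(50)
        adj[:8] = 0.01   # 8 true calls
        adj[20:22] = 0.01  # 2 false calls
        fdp, tpr = fdp_tpr_gene_level(self.table(adj), self.make_truth(is_de), 0.1)
        assert fdp == pytest.approx(0.2)
        assert tpr == pytest.approx(0.4)


class TestLabelCellGroups:
    def test_positive_rule(self):
        group = np.arange(20)
        changed = np.arange(14)  # 70%, >= 10 cells
        assert label_cell_groups(group, changed) == "positive"

    def test_negative_rule(self):
        group = np.arange(100)
        changed = np.arange(5)  # 5%
        assert label_cell_groups(group, changed) == "negative"

    def test_indeterminate_band(self):
        group = np.arange(100)
        changed = np.arange(30)  # 30%
        assert label_cell_groups(group, changed) == "indeterminate"

    def test_fallback_marks_largest_fraction_positive(self):
        group = np.arange(100)
        changed = np.arange(30)
        assert label_cell_groups(group, changed, best_fraction_fallback=True) == "positive"


class TestPredictionL2:
    def test_identity_gives_zero(self, rng):
        x = rng.standard_normal((10, 20))
        out = prediction_l2_metrics(x, x)
        assert out.loc[0, "l2_mean"] == pytest.approx(0.0)
        assert out.loc[0, "l2_sd"] == pytest.approx(0.0)

    def test_constant_shift(self, rng):
        x = rng.standard_normal((16, 30))
        out = prediction_l2_metrics(x + 0.5, x)
        assert out.loc[0, "l2_mean"] == pytest.approx(np.sqrt(16) * 0.5)

    def test_condition_mean_beats_identity_prediction(self, rng):
        g, n = 12, 400
        base = rng.standard_normal((g, n))
        effect = rng.standard_normal((g, 1))
        obs_b = base + effect + 0.1 * rng.standard_normal((g, n))
        identity_pred = base  # ignores the condition effect
        oracle_pred = base + effect
        e_id = prediction_l2_metrics(identity_pred, obs_b).loc[0, "l2_mean"]
        e_or = prediction_l2_metrics(oracle_pred, obs_b).loc[0, "l2_mean"]
        assert e_or < e_id

    def test_empty_cell_type_raises(self, rng):
        x = rng.standard_normal((4, 6))
        with pytest.raises(ValueError):
            prediction_l2_metrics(x, x, cell_types=(np.repeat("a", 6), np.repeat("b", 6)))
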