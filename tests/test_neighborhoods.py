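import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from lemur.neighborhoods import (
    bh_adjust,
    lm_test,
    nb_glm_lrt,
    pseudobulk_aggregate,
    sample_directions,
    select_neighborhoods,
)


class TestSampleDirections:
    def test_unit_norm_and_determinism(self):
        d1 = sample_directions(30, 100, seed=7)
        d2 = sample_directions(30, 100, seed=7)
        d3 = sample_directions(30, 100, seed=8)
        assert np.allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-12)
        assert np.array_equal(d1, d2)
        assert not np.array_equal(d1, d3)

    def test_mean_abs_dot_matches_monte_carlo(self):
        d = sample_directions(30, 100, seed=0)
        dots = np.abs(d @ d.T)[np.triu_indices(100, 1)]
        rng = np.random.default_rng(1)
        u = rng.standard_normal((4000, 30))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        mc = np.abs(np.sum(u[:2000] * u[2000:], axis=1)).mean()
        assert abs(dots.mean() - mc) < 3 * dots.std() / np.sqrt(len(dots)) + 0.02


def brute_force_best(delta, t, min_cells):
    """All prefixes of both orderings of a single projection."""
    sd = delta.std(ddof=1)
    best = -np.inf
    for side in (+1, -1):
        order = np.argsort(-side * t, kind="stable")
        csum = np.cumsum(delta[order])
        for n in range(min_cells, len(t) + 1):
            score = abs(csum[n - 1]) / (sd * np.sqrt(n))
            best = max(best, score)
    return best


class TestSelectNeighborhoods:
    def test_constant_positive_delta_selects_everything(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 50))
        delta = np.ones((1, 50)) + rng.normal(0, 1e-6, (1, 50))
        (nbh,) = select_neighborhoods(delta, z, sample_directions(3, 10, 0), min_cells=5)
        assert nbh.contains(z).sum() == 50

    def test_zero_delta_yields_none(self):
        z = np.random.default_rng(0).standard_normal((2, 30))
        (nbh,) = select_neighborhoods(np.zeros((1, 30)), z, sample_directions(2, 5, 0))
        assert nbh is None

    def test_matches_brute_force_per_direction(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((4, 60))
        delta = rng.standard_normal((3, 60))
        directions = sample_directions(4, 7, seed=2)
        nbhs = select_neighborhoods(delta, z, directions, min_cells=5)
        for g in range(3):
            oracle = max(
                brute_force_best(delta[g], v @ z, 5) for v in directions
            )
            assert abs(nbhs[g].score - oracle) < 1e-10

    def test_two_cluster_recovery(self):
        """Delta concentrated in one latent cluster: the selected half-space
        overlaps that cluster almost perfectly."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            labels = rng.integers(0, 2, n)
            z = rng.normal(0, 0.3, (3, n))
            z[0] += labels * 4.0 - 2.0
            delta = (labels == 1).astype(float)[None, :] + rng.normal(0, 0.1, (1, n))
            (nbh,) = select_neighborhoods(
                delta, z, sample_directions(3, 50, seed), min_cells=10
            )
            member = nbh.contains(z)
            inter = np.sum(member & (labels == 1))
            union = np.sum(member | (labels == 1))
            assert inter / union > 0.9

    def test_membership_reproducible_from_direction_and_threshold(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((3, 80))
        delta = rng.standard_normal((2, 80))
        nbhs = select_neighborhoods(delta, z, sample_directions(3, 20, 3), min_cells=10)
        for nbh in nbhs:
            t = nbh.direction @ z
            expected = t >= nbh.threshold if nbh.side > 0 else t <= nbh.threshold
            assert np.array_equal(nbh.contains(z), expected)

    def test_contrast_direction_variant(self):
        rng = np.random.default_rng(2)
        n = 150
        z = rng.standard_normal((4, n))
        delta = 2.0 * z[1][None, :] + rng.normal(0, 0.1, (1, n))
        (nbh,) = select_neighborhoods(
            delta, z, min_cells=10, selection_procedure="contrast"
        )
        # the gene-specific direction aligns with the covariance of delta and z
        v_expected = (delta @ z.T).ravel()
        v_expected /= np.linalg.norm(v_expected)
        assert abs(abs(nbh.direction @ v_expected) - 1.0) < 1e-10


class TestPseudobulk:
    def test_single_cell_samples_pass_through(self):
        values = np.arange(6.0).reshape(2, 3)
        agg, n = pseudobulk_aggregate(values, np.arange(3), np.array(["a", "b", "c"]))
        assert np.array_equal(agg, values)
        assert np.array_equal(n, [1, 1, 1])

    def test_counts_mode_sums(self):
        counts = np.array([[1, 3], [2, 4]])
        agg, n = pseudobulk_aggregate(counts, np.array([0, 1]), np.array(["s", "s"]))
        assert np.array_equal(agg[:, 0], [4, 6])
        assert n[0] == 2

    def test_additive_over_disjoint_cell_sets(self, rng):
        values = rng.poisson(5, (4, 30)).astype(float)
        samples = np.array(["s%d" % (i % 3) for i in range(30)])
        a = np.arange(10)
        b = np.arange(10, 30)
        agg_a, _ = pseudobulk_aggregate(values, a, samples)
        agg_b, _ = pseudobulk_aggregate(values, b, samples)
        agg_all, _ = pseudobulk_aggregate(values, np.arange(30), samples)
        assert np.allclose(agg_a + agg_b, agg_all)

    def test_empty_sample_kept_with_zero_count(self):
        values = np.ones((1, 4))
        agg, n = pseudobulk_aggregate(
            values, np.array([0, 1]), np.array(["a", "a", "b", "b"]),
            sample_levels=np.array(["a", "b"]),
        )
        assert n[1] == 0 and agg[0, 1] == 0


class TestNbGlmLrt:
    design = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])

    def test_identical_groups_give_null_result(self):
        y = np.tile([10.0, 10, 10, 10, 10, 10], (3, 1))
        res = nb_glm_lrt(y, self.design, 1)
        assert np.allclose(res["lfc"], 0.0, atol=1e-6)
        assert np.allclose(res["p_value"], 1.0, atol=1e-6)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(0)
        g = 2000
        mu = rng.lognormal(2, 1, size=(g, 1)) * np.ones((1, 6))
        y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu))
        p = nb_glm_lrt(y, self.design, 1)["p_value"].to_numpy()
        assert st.kstest(p, "uniform").statistic < 0.1

    def test_strong_effect_recovers_log2_fold_change(self):
        rng = np.random.default_rng(1)
        s = 40
        x = np.column_stack([np.ones(s), np.tile([0, 1.0], s // 2)])
        mu = 10.0 * 4.0 ** x[:, 1]
        y = rng.poisson(np.tile(mu, (5, 1)))
        res = nb_glm_lrt(y, x, 1)
        assert np.allclose(res["lfc"], 2.0, atol=0.15)

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        s = 8
        x = np.column_stack([np.ones(s), np.tile([0, 1.0], s // 2)])
        g = 15
        mu = rng.lognormal(3, 0.8, size=(g, 1)) * np.exp(0.4 * x[:, 1])[None, :]
        y = rng.poisson(rng.gamma(1 / 0.3, 0.3 * mu))
        off = rng.normal(0, 0.1, size=s)
        mine = nb_glm_lrt(
            y, x, 1, offsets=np.tile(off, (g, 1)), prior_n=0, cox_reid=False,
            reference="chi2",
        )
        for i in range(g):
            nbm = sm.NegativeBinomial(y[i], x, offset=off).fit(disp=0, maxiter=200)
            alpha = max(nbm.params[-1], 1e-8)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(y[i], x, family=fam, offset=off).fit()
            red = sm.GLM(y[i], x[:, :1], family=fam, offset=off).fit()
            p_sm = st.chi2.sf(max(2 * (full.llf - red.llf), 0.0), 1)
            assert abs(p_sm - mine["p_value"][i]) < 0.02
            assert abs(full.params[1] / np.log(2) - mine["lfc"][i]) < 5e-3

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            nb_glm_lrt(np.ones((2, 2)), self.design[:2], 1)


class TestLmTest:
    design = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])

    def test_identical_means_give_p_one_region(self):
        y = np.tile([2.0, 2, 2, 2, 2, 2], (2, 1))
        res = lm_test(y, self.design, 1)
        assert np.allclose(res["t"], 0.0, atol=1e-10)
        assert np.allclose(res["p_value"], 1.0, atol=1e-10)

    def test_matches_two_sample_t_test(self):
        y = np.array([[1.0, 2, 3, 4, 5, 6]])
        res = lm_test(y, self.design, 1)
        t_ref, p_ref = st.ttest_ind([4.0, 5, 6], [1.0, 2, 3], equal_var=True)
        assert abs(res["t"][0] - t_ref) < 1e-10
        assert abs(res["p_value"][0] - p_ref) < 1e-12

    def test_shift_invariance(self, rng):
        y = rng.standard_normal((4, 6))
        r1 = lm_test(y, self.design, 1)
        r2 = lm_test(y + 100.0, self.design, 1)
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-10)


class TestBhAdjust:
    def test_hand_case(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_single_value_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_nan_entries_preserved_and_excluded(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.02, 0.04])

    def test_matches_brute_force_step_up(self, rng):
        p = rng.uniform(size=200)
        out = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert np.allclose(out, brute, atol=1e-12)

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=50)
        out = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))
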