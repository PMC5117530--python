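"""Moderated two-group testing: group stats, prior estimation, BH, calls."""

import math

import numpy as np
import pytest
from scipy import stats

from stromasig import (GroupContrast, Prior, bh_adjust, call_de, de_analysis,
                       estimate_prior, group_stats, moderated_test)
from stromasig.diffexpr import GroupStats

from conftest import make_matrix


def bruteforce_bh(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        running = min(running, p[order[pos]] * m / (pos + 1))
        q[order[pos]] = min(running, 1.0)
    return q


class TestGroupStats:
    def test_identical_groups_zero_logfc_zero_variance(self):
        mat = make_matrix([[5.0, 5.0, 5.0, 5.0]])
        c = GroupContrast("c", ["s1", "s2"], ["s3", "s4"])
        gs = group_stats(mat, c)
        assert gs.logfc[0] == 0.0 and gs.s2[0] == 0.0

    def test_hand_arithmetic(self):
        # A = {4, 6}, B = {1, 3}: logFC = 3, pooled s2 = 2, df = 2
        mat = make_matrix([[4.0, 6.0, 1.0, 3.0]])
        gs = group_stats(mat, GroupContrast("c", ["s1", "s2"], ["s3", "s4"]))
        assert gs.logfc[0] == pytest.approx(3.0)
        assert gs.s2[0] == pytest.approx(2.0)
        assert gs.df_resid == 2

    def test_matches_bruteforce_on_random_instance(self, rng):
        mat = make_matrix(rng.normal(size=(500, 9)))
        a, b = ["s1", "s2", "s3", "s4"], ["s5", "s6", "s7", "s8", "s9"]
        gs = group_stats(mat, GroupContrast("c", a, b))
        for i in range(500):
            va = mat.data.iloc[i][a].to_numpy()
            vb = mat.data.iloc[i][b].to_numpy()
            assert gs.logfc[i] == pytest.approx(va.mean() - vb.mean())
            pooled = (((va - va.mean()) ** 2).sum()
                      + ((vb - vb.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
            assert gs.s2[i] == pytest.approx(pooled)

    def test_single_column_group_rejected(self):
        with pytest.raises(ValueError):
            GroupContrast("c", ["s1"], ["s2", "s3"])


class TestEstimatePrior:
    def test_constant_variances_give_infinite_d0(self):
        prior = estimate_prior(np.full(100, 0.25), df_resid=10)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.ones(9), df_resid=4)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(100), df_resid=4)

    def test_recovery_from_scaled_inv_chisq(self):
        # the moment estimator must recover the generating hyperparameters
        d0_true, s0_true, dg, n_genes = 4.0, 0.05, 12, 5000
        d0_hats, s0_hats = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n_genes)
            s2 = sigma2 * rng.chisquare(dg, n_genes) / dg
            prior = estimate_prior(s2, dg)
            d0_hats.append(prior.d0)
            s0_hats.append(prior.s0_sq)
        assert abs(np.median(d0_hats) - d0_true) / d0_true < 0.15
        assert abs(np.median(s0_hats) - s0_true) / s0_true < 0.15


class TestModeratedTest:
    @staticmethod
    def _stats(rng, n=20, na=4, nb=4):
        mat = make_matrix(rng.normal(size=(n, na + nb)))
        c = GroupContrast("c", [f"s{i + 1}" for i in range(na)],
                          [f"s{i + 1}" for i in range(na, na + nb)])
        return group_stats(mat, c)

    def test_d0_zero_is_ordinary_pooled_t(self, rng):
        gs = self._stats(rng)
        t_mod, _ = moderated_test(gs, Prior(d0=0.0, s0_sq=1.0))
        # oracle: scipy's pooled-variance two-sample t on the same data
        se = np.sqrt(gs.s2 * (1 / gs.n_a + 1 / gs.n_b))
        expected = gs.logfc / se
        np.testing.assert_allclose(t_mod, expected, rtol=1e-12)

    def test_d0_infinite_uses_prior_variance_everywhere(self, rng):
        gs = self._stats(rng)
        t_mod, p = moderated_test(gs, Prior(d0=math.inf, s0_sq=0.5))
        expected = gs.logfc / np.sqrt(0.5 * (1 / gs.n_a + 1 / gs.n_b))
        np.testing.assert_allclose(t_mod, expected, rtol=1e-12)
        # normal reference distribution in the infinite-df limit
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(expected)),
                                   rtol=1e-9)

    def test_matches_independent_implementation(self, rng):
        # dual-route check of the posterior-variance formulas on a fixed
        # 20-gene instance
        gs = self._stats(rng)
        d0, s0 = 3.0, 0.2
        t_mod, p = moderated_test(gs, Prior(d0=d0, s0_sq=s0))
        for i in range(20):
            s2_post = (d0 * s0 + gs.df_resid * gs.s2[i]) / (d0 + gs.df_resid)
            t_exp = gs.logfc[i] / math.sqrt(
                s2_post * (1 / gs.n_a + 1 / gs.n_b))
            p_exp = 2 * stats.t.sf(abs(t_exp), d0 + gs.df_resid)
            assert t_mod[i] == pytest.approx(t_exp, rel=1e-12)
            assert p[i] == pytest.approx(p_exp, rel=1e-10)

    def test_moderated_t_converges_to_ordinary_t(self, rng):
        gs = self._stats(rng)
        t_ord, _ = moderated_test(gs, Prior(d0=0.0, s0_sq=1.0))
        t_small, _ = moderated_test(gs, Prior(d0=1e-14, s0_sq=1.0))
        np.testing.assert_allclose(t_small, t_ord, atol=1e-12)

    def test_zero_posterior_variance_warns(self):
        gs = GroupStats(gene_ids=["g"], logfc=np.array([1.0]),
                        s2=np.array([0.0]), df_resid=2, n_a=2, n_b=2)
        with pytest.warns(UserWarning):
            _, p = moderated_test(gs, Prior(d0=0.0, s0_sq=0.0))
        assert p[0] > 0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    def test_uniformly_spaced_example(self):
        # p = (0.01, 0.02, 0.03, 0.04): every p_(i) * 4 / i = 0.04
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_equals_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            np.testing.assert_allclose(bh_adjust(p), bruteforce_bh(p),
                                       rtol=1e-12, atol=1e-15)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDe:
    def test_nothing_called_when_fdr_is_one(self, rng):
        mat = make_matrix(rng.normal(size=(30, 8)))
        c = GroupContrast("c", ["s1", "s2", "s3", "s4"],
                          ["s5", "s6", "s7", "s8"])
        result = de_analysis(mat, c)
        result.table["fdr"] = 1.0
        up, down = call_de(result)
        assert not up and not down

    def test_boundary_fdr_excluded(self, rng):
        mat = make_matrix(rng.normal(size=(30, 8)))
        c = GroupContrast("c", ["s1", "s2", "s3", "s4"],
                          ["s5", "s6", "s7", "s8"])
        result = de_analysis(mat, c)
        result.table["fdr"] = 0.05
        up, down = call_de(result, alpha=0.05)
        assert not up and not down

    def test_invalid_alpha_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(30, 8)))
        c = GroupContrast("c", ["s1", "s2", "s3", "s4"],
                          ["s5", "s6", "s7", "s8"])
        result = de_analysis(mat, c)
        with pytest.raises(ValueError):
            call_de(result, alpha=1.5)

    def test_planted_contrast_recall(self):
        # 2000 genes, 40 planted at logFC 1.5, 15 vs 15 samples
        rng = np.random.default_rng(99)
        n, k = 2000, 40
        d0, s0 = 4.0, 0.05
        sigma2 = s0 * d0 / rng.chisquare(d0, n)
        values = rng.normal(0, 1, (n, 30)) * np.sqrt(sigma2)[:, None]
        values[:k, :15] += 1.5
        mat = make_matrix(values)
        c = GroupContrast("c", [f"s{i + 1}" for i in range(15)],
                          [f"s{i + 1}" for i in range(15, 30)])
        up, _ = call_de(de_analysis(mat, c))
        planted = {f"G{i + 1}" for i in range(k)}
        assert len(up & planted) / k >= 0.9
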