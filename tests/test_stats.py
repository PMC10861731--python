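"""Correlation, bootstrap, cluster-permutation and PLS/VIP tests."""

import numpy as np
import pytest
from scipy import stats as sps

from megspect import (
    ConstantInputError,
    DegeneratePredictorError,
    RegionAdjacency,
    SchemaError,
    bootstrap_spearman,
    cluster_permutation_correlation,
    confound_screen,
    pls1_vip,
    spearman_rho,
    t_from_rho,
)
from megspect.stats import VIPComparison

from _oracles import brute_cluster_permutation


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(30)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self, rng):
        x = rng.standard_normal(30)
        assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4, rho = 1 - 6*4/(5*(25-1)) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_ties_match_scipy(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float) + 0.3 * x
        assert spearman_rho(x, y) == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_missing_pairs_dropped_listwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestTFromRho:
    def test_zero_rho_gives_zero(self):
        assert t_from_rho(0.0, 10) == 0.0

    def test_printed_formula_value(self):
        assert t_from_rho(0.5, 6) == pytest.approx(0.5 * 2 / np.sqrt(0.75), abs=1e-10)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        assert np.allclose(t_from_rho(-r, 20), -t_from_rho(r, 20))

    def test_saturated_rho_warns_and_returns_inf(self):
        with pytest.warns(RuntimeWarning):
            assert t_from_rho(1.0, 10) == np.inf


class TestBootstrap:
    def test_identity_pair_significant_positive(self, rng):
        x = rng.standard_normal(30)
        b = bootstrap_spearman(x, x, n_boot=500, seed=0)
        assert b.significant and b.ci_low > 0

    def test_deterministic_given_seed(self, rng):
        x, y = rng.standard_normal((2, 40))
        a = bootstrap_spearman(x, y, n_boot=500, seed=7)
        b = bootstrap_spearman(x, y, n_boot=500, seed=7)
        assert (a.ci_low, a.ci_high, a.rho_mean) == (b.ci_low, b.ci_high, b.rho_mean)

    def test_ci_brackets_mean(self, rng):
        x, y = rng.standard_normal((2, 60))
        b = bootstrap_spearman(x, y, n_boot=2000, seed=3)
        assert b.ci_low <= b.rho_mean <= b.ci_high

    def test_listwise_deletion_adjusts_n(self, rng):
        x, y = rng.standard_normal((2, 30))
        x[::7] = np.nan
        b = bootstrap_spearman(x, y, n_boot=200, seed=1)
        assert b.n == int(np.isfinite(x).sum())


class TestClusterPermutation:
    def make_data(self, rng, n=12, n_regions=5, effect=None):
        P = rng.standard_normal((n, n_regions))
        c = rng.standard_normal(n)
        if effect:
            for r in effect:
                P[:, r] += 1.2 * c[:]
        return P, c

    def test_matches_brute_force_on_line_graph(self, rng, line_graph_5):
        P, c = self.make_data(rng, effect=[1, 2])
        perms = np.array([rng.permutation(12) for _ in range(200)])
        ours = cluster_permutation_correlation(
            P, c, line_graph_5, permutations=perms
        )
        brute = brute_cluster_permutation(P, c, line_graph_5.edges, perms)
        assert len(ours) == len(brute)
        ours_set = {(r.sign, tuple(sorted(r.member_indices))): r for r in ours}
        for b in brute:
            key = (b["sign"], tuple(b["members"]))
            assert key in ours_set
            r = ours_set[key]
            assert r.sum_t == pytest.approx(b["sum_t"], abs=1e-9)
            assert r.p_value == pytest.approx(b["p"], abs=1e-12)

    def test_rank_invariance_under_monotone_covariate_transform(self, rng, line_graph_5):
        P, c = self.make_data(rng, n=20, effect=[0, 1])
        perms = np.array([rng.permutation(20) for _ in range(150)])
        a = cluster_permutation_correlation(P, c, line_graph_5, permutations=perms)
        b = cluster_permutation_correlation(
            P, np.exp(2.0 * c), line_graph_5, permutations=perms
        )
        assert [(r.sign, r.members, r.p_value, r.sum_t) for r in a] == [
            (r.sign, r.members, r.p_value, r.sum_t) for r in b
        ]

    def test_region_relabeling_permutes_membership_only(self, rng, line_graph_5):
        P, c = self.make_data(rng, n=16, effect=[2, 3])
        perms = np.array([rng.permutation(16) for _ in range(150)])
        a = cluster_permutation_correlation(P, c, line_graph_5, permutations=perms)
        order = np.array([4, 2, 0, 1, 3])
        adj2 = line_graph_5.relabeled(order)
        b = cluster_permutation_correlation(P[:, order], c, adj2, permutations=perms)
        key = lambda rs: sorted((r.sign, round(r.sum_t, 9), round(r.p_value, 12),
                                 tuple(sorted(r.members))) for r in rs)
        assert key(a) == key(b)

    def test_deterministic_given_seed(self, rng, line_graph_5):
        P, c = self.make_data(rng, n=15, effect=[0])
        a = cluster_permutation_correlation(P, c, line_graph_5, n_perm=150, seed=5)
        b = cluster_permutation_correlation(P, c, line_graph_5, n_perm=150, seed=5)
        assert [(r.members, r.p_value) for r in a] == [(r.members, r.p_value) for r in b]

    def test_p_monotone_in_cluster_sum(self):
        from megspect.stats import _empirical_p

        null = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        ps = [_empirical_p(null, s, "positive") for s in (0.5, 1.5, 2.5, 6.0)]
        assert ps == sorted(ps, reverse=True)
        ns = [_empirical_p(-null, s, "negative") for s in (-0.5, -1.5, -2.5, -6.0)]
        assert ns == sorted(ns, reverse=True)

    def test_too_few_subjects_rejected(self, rng, line_graph_5):
        P, c = self.make_data(rng, n=8)
        with pytest.raises(SchemaError):
            cluster_permutation_correlation(P, c, line_graph_5, n_perm=100, seed=0)

    def test_region_count_mismatch_rejected(self, rng, line_graph_5):
        P = rng.standard_normal((12, 4))
        with pytest.raises(SchemaError):
            cluster_permutation_correlation(
                P, rng.standard_normal(12), line_graph_5, n_perm=100, seed=0
            )


class TestPLSVIP:
    def test_informative_predictor_dominates(self, rng):
        x1 = rng.standard_normal(100)
        x2 = rng.standard_normal(100)
        y = x1 + 0.05 * rng.standard_normal(100)
        comp = pls1_vip(y, np.column_stack([x1, x2]))
        assert comp.vip_variable > comp.vip_age and not comp.exclude

    def test_exchangeable_predictors_equal_vip(self, rng):
        x1 = rng.standard_normal(2000)
        x2 = rng.standard_normal(2000)
        y = x1 + x2
        comp = pls1_vip(y, np.column_stack([x1, x2]))
        # the sqrt(2)|w_j|/||w|| identity is exact under exact symmetry
        sym = pls1_vip(x1 + x2, np.column_stack([x1 + x2, x1 + x2 + 0.0]))
        assert sym.vip_variable == pytest.approx(1.0, abs=1e-9)
        assert abs(comp.vip_variable - comp.vip_age) < 0.1

    def test_one_component_identity(self, rng):
        for _ in range(20):
            X = rng.standard_normal((30, 2))
            y = rng.standard_normal(30)
            comp = pls1_vip(y, X)
            assert comp.vip_variable**2 + comp.vip_age**2 == pytest.approx(2.0, abs=1e-8)

    def test_matches_sklearn_first_component_weights(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((60, 2))
        y = X @ np.array([0.8, -0.3]) + 0.5 * rng.standard_normal(60)
        comp = pls1_vip(y, X)
        pls = PLSRegression(n_components=1, scale=True).fit(X, y)
        w = pls.x_weights_[:, 0]
        vip = np.sqrt(2.0) * np.abs(w) / np.linalg.norm(w)
        assert comp.vip_variable == pytest.approx(vip[0], abs=1e-8)
        assert comp.vip_age == pytest.approx(vip[1], abs=1e-8)

    def test_constant_predictor_rejected(self, rng):
        y = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        with pytest.raises(DegeneratePredictorError):
            pls1_vip(y, X)


class TestConfoundScreen:
    def make_cluster(self, rng, line_graph_5):
        P, c = TestClusterPermutation().make_data(rng, n=20, effect=[0, 1, 2])
        return cluster_permutation_correlation(
            P, c, line_graph_5, n_perm=150, seed=2
        )

    def test_no_exclusion_is_identity(self, rng, line_graph_5):
        clusters = self.make_cluster(rng, line_graph_5)
        vip = {
            m: VIPComparison(1.2, 0.8, False, m)
            for cl in clusters
            for m in cl.members
        }
        out = confound_screen(clusters, vip)
        assert [(c.members, c.sum_t, c.p_value) for c in out] == [
            (c.members, c.sum_t, c.p_value) for c in clusters
        ]

    def test_full_exclusion_drops_cluster(self, rng, line_graph_5):
        clusters = self.make_cluster(rng, line_graph_5)
        vip = {
            m: VIPComparison(0.5, 1.3, True, m)
            for cl in clusters
            for m in cl.members
        }
        assert confound_screen(clusters, vip) == []

    def test_partial_exclusion_recomputes_means(self, rng, line_graph_5):
        clusters = [cl for cl in self.make_cluster(rng, line_graph_5) if len(cl.members) >= 2]
        assert clusters, "fixture should yield a multi-region cluster"
        cl = clusters[0]
        drop = cl.members[0]
        vip = {m: VIPComparison(0.5, 1.3, m == drop, m) for m in cl.members}
        out = confound_screen([cl], vip)[0]
        keep = [m != drop for m in cl.members]
        assert out.members == [m for m in cl.members if m != drop]
        assert out.mean_t == pytest.approx(float(cl.member_t[keep].mean()))
        assert out.mean_rho == pytest.approx(float(cl.member_rho[keep].mean()))
        assert out.p_value == cl.p_value  # screen is post hoc
        assert out.n_excluded == 1

    def test_missing_vip_for_member_rejected(self, rng, line_graph_5):
        clusters = self.make_cluster(rng, line_graph_5)
        with pytest.raises(SchemaError):
            confound_screen(clusters, {})
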