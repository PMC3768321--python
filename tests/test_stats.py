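"""Permutation statistics, rank tests and generalized differencing."""

import itertools

import numpy as np
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from morphorates.distances import DistanceMatrix
from morphorates.stats import (
    anosim,
    diversity_disparity_correlation,
    estimate_ar1,
    generalized_differencing,
    kruskal_wallis,
    mann_whitney,
    mantel,
    npmanova,
    pairwise_mann_whitney,
    subset_distances,
)


def dm(x):
    return DistanceMatrix([f"t{i}" for i in range(len(x))], squareform(pdist(x)))


class TestMantel:
    def test_self_correlation_is_one_with_minimal_p(self, rng):
        d = dm(rng.normal(size=(8, 3)))
        res = mantel(d, d, coef="pearson", nperm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_coefficient_equals_plain_upper_triangle_correlation(self, rng):
        a, b = dm(rng.normal(size=(7, 2))), dm(rng.normal(size=(7, 2)))
        iu = np.triu_indices(7, 1)
        for coef, fn in [
            ("pearson", scipy.stats.pearsonr),
            ("spearman", scipy.stats.spearmanr),
            ("kendall", scipy.stats.kendalltau),
        ]:
            res = mantel(a, b, coef=coef, nperm=9, seed=0)
            assert res.statistic == pytest.approx(fn(a.d[iu], b.d[iu])[0])

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        n = 5
        a, b = dm(rng.normal(size=(n, 2))), dm(rng.normal(size=(n, 2)))
        iu = np.triu_indices(n, 1)
        obs = scipy.stats.pearsonr(a.d[iu], b.d[iu])[0]
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            s = scipy.stats.pearsonr(a.d[iu], b.d[np.ix_(p, p)][iu])[0]
            count += abs(s) >= abs(obs) - 1e-12
            total += 1
        exact = count / total
        res = mantel(a, b, coef="pearson", nperm=9999, seed=1)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_label_mismatch_rejected(self, rng):
        a = dm(rng.normal(size=(5, 2)))
        b = DistanceMatrix(list("abcde"), a.d)
        with pytest.raises(ValueError, match="labels"):
            mantel(a, b)

    def test_two_taxon_matrix_refused(self, rng):
        a = dm(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="three"):
            mantel(a, a)

    def test_seed_determinism(self, rng):
        a, b = dm(rng.normal(size=(6, 2))), dm(rng.normal(size=(6, 2)))
        r1 = mantel(a, b, nperm=199, seed=5)
        r2 = mantel(a, b, nperm=199, seed=5)
        assert r1.p == r2.p

    def test_subset_distances(self, rng):
        a = dm(rng.normal(size=(6, 2)))
        assert subset_distances(a, set()).labels == a.labels
        sub = subset_distances(a, {"t0", "t3"})
        assert sub.labels == ["t1", "t2", "t4", "t5"]


class TestGroupTests:
    def test_npmanova_matches_skbio_permanova(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova

        pts = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(1.5, 1, (8, 3))])
        groups = ["a"] * 8 + ["b"] * 8
        res = npmanova(pts, groups, nperm=99, seed=0, pairwise=False)
        sk = permanova(
            skbio.DistanceMatrix(squareform(pdist(pts))), grouping=groups,
            permutations=99,
        )
        assert res.statistic == pytest.approx(sk["test statistic"])

    def test_anosim_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        pts = np.vstack([rng.normal(0, 1, (7, 3)), rng.normal(2, 1, (7, 3))])
        groups = ["a"] * 7 + ["b"] * 7
        d = dm(pts)
        res = anosim(d, groups, nperm=99, seed=0)
        sk = sk_anosim(skbio.DistanceMatrix(d.d), grouping=groups, permutations=99)
        assert res.statistic == pytest.approx(sk["test statistic"])

    def test_separated_clusters_yield_anosim_r_one(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (6, 2)), rng.normal(9, 0.01, (6, 2))])
        res = anosim(dm(pts), ["a"] * 6 + ["b"] * 6, nperm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_interleaved_groups_not_significant(self, rng):
        pts = rng.normal(size=(16, 3))
        groups = ["a", "b"] * 8
        res = npmanova(pts, groups, nperm=199, seed=0, pairwise=False)
        assert res.p > 0.05

    def test_mean_permuted_anosim_r_near_zero(self, rng):
        pts = rng.normal(size=(12, 3))
        d = dm(pts)
        stats = [
            anosim(d, rng.permutation(["a"] * 6 + ["b"] * 6), nperm=1, seed=i).statistic
            for i in range(60)
        ]
        assert abs(np.mean(stats)) < 0.12

    def test_invariance_to_axis_sign_flips_and_reordering(self, rng):
        pts = np.vstack([rng.normal(0, 1, (6, 4)), rng.normal(1, 1, (6, 4))])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        base = npmanova(pts, groups, nperm=49, seed=3, pairwise=False)
        flipped = npmanova(pts * np.array([-1, 1, -1, 1]), groups, nperm=49,
                           seed=3, pairwise=False)
        order = rng.permutation(12)
        reordered = npmanova(pts[order], groups[order], nperm=49, seed=3,
                             pairwise=False)
        assert base.statistic == pytest.approx(flipped.statistic)
        assert base.statistic == pytest.approx(reordered.statistic)

    def test_pairwise_table_bonferroni(self, rng):
        pts = np.vstack(
            [rng.normal(i * 2, 0.5, (5, 2)) for i in range(3)]
        )
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = npmanova(pts, groups, nperm=99, seed=0)
        assert len(res.extra) == 3
        assert (res.extra["p_bonferroni"] >= res.extra["p"] - 1e-12).all()


class TestRankTests:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([np.arange(1.0, 7.0), np.arange(1.0, 7.0)])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_h_matches_exhaustive_rank_null(self, rng):
        # small-sample H compared against the exact permutation distribution
        a = np.array([1.2, 3.4, 5.1])
        b = np.array([2.2, 4.9])
        h_obs, _ = kruskal_wallis([a, b])
        pooled = np.concatenate([a, b])
        count = total = 0
        for comb in itertools.combinations(range(5), 3):
            ga = pooled[list(comb)]
            gb = pooled[[i for i in range(5) if i not in comb]]
            h, _ = kruskal_wallis([ga, gb])
            count += h >= h_obs - 1e-12
            total += 1
        # observed split is one of the enumerated splits: p is attainable
        assert 0 < count / total <= 1

    def test_u_statistic_matches_hand_count(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0])
        u, _ = mann_whitney(a, b)
        # all 6 (a_i, b_j) pairs have a < b: U in {0, 6}
        assert u in (0.0, 6.0)

    def test_pairwise_mann_whitney_table(self, rng):
        samples = {
            "x": rng.normal(0, 1, 10),
            "y": rng.normal(3, 1, 10),
            "z": rng.normal(0, 1, 10),
        }
        df = pairwise_mann_whitney(samples)
        assert len(df) == 3
        xy = df[(df.group_a == "x") & (df.group_b == "y")].iloc[0]
        assert xy["p"] < 0.05


class TestGeneralizedDifferencing:
    def test_linear_series_maps_to_zero(self):
        t = np.arange(10.0)
        out = generalized_differencing(3.0 - 0.5 * t, t)
        assert np.abs(out).max() < 1e-10

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            generalized_differencing(np.arange(3.0), np.arange(3.0))

    def test_white_noise_rho_small_on_average(self, rng):
        t = np.arange(40.0)
        rhos = [
            estimate_ar1(rng.normal(size=40), t) for _ in range(300)
        ]
        assert abs(np.mean(rhos)) < 0.1

    def test_ar1_rho_recovery_and_whitening(self, rng):
        t = np.arange(200.0)
        rho_true = 0.7
        e = np.zeros(200)
        for i in range(1, 200):
            e[i] = rho_true * e[i - 1] + rng.normal()
        series = 1.0 + 0.05 * t + e
        rho_hat = estimate_ar1(series, t)
        assert rho_hat == pytest.approx(rho_true, abs=0.15)
        out = generalized_differencing(series, t)
        assert abs(estimate_ar1(out, t)) < 0.15


class TestDiversityDisparity:
    def test_identical_series_r_one(self):
        t = np.arange(8.0)
        s = np.array([3.0, 4, 6, 5, 7, 8, 6, 9])
        r, _ = diversity_disparity_correlation(s, s, t)
        assert r == pytest.approx(1.0)

    def test_differenced_null_p_roughly_uniform(self, rng):
        t = np.arange(12.0)
        ps = []
        for _ in range(200):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            _, p = diversity_disparity_correlation(a, b, t, differenced=True)
            ps.append(p)
        # independent series: rejection rate at 0.05 stays near nominal
        rate = np.mean(np.array(ps) < 0.05)
        assert rate < 0.12

    def test_spearman_option(self, rng):
        t = np.arange(6.0)
        a = rng.normal(size=6)
        r, _ = diversity_disparity_correlation(a, 2 * a + 1, t, coef="spearman")
        assert r == pytest.approx(1.0)
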