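"""Rank tests, permutation GLM, TFCE and cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from petnorm import (
    extract_clusters,
    kruskal_eta2,
    mann_whitney_effect,
    permutation_glm,
    scheirer_ray_hare,
    spearman_clinical,
    tfce_enhance,
)
from petnorm.imaging import BrainMask
from petnorm.simulate import default_grid


class TestScheirerRayHare:
    def test_degenerate_all_equal(self):
        res = scheirer_ray_hare(
            np.ones(12), ["a", "b"] * 6, ["x"] * 6 + ["y"] * 6
        )
        for r in res.values():
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_single_level_factor_reduces_to_kruskal(self, rng):
        values = rng.standard_normal(30)
        values[10:20] += 0.8
        groups = np.repeat(["g1", "g2", "g3"], 10)
        res = scheirer_ray_hare(values, groups, ["only"] * 30)
        h_kw, _ = sps.kruskal(values[:10], values[10:20], values[20:])
        assert res["A"].statistic == pytest.approx(h_kw, abs=1e-10)

    def test_reduction_with_ties(self, rng):
        values = np.round(rng.standard_normal(24), 1)  # force ties
        groups = np.repeat(["g1", "g2"], 12)
        res = scheirer_ray_hare(values, groups, ["only"] * 24)
        h_kw, _ = sps.kruskal(values[:12], values[12:])
        assert res["A"].statistic == pytest.approx(h_kw, abs=1e-10)

    def test_chi2_p_close_to_permutation_p(self):
        # 3x2 design, n = 8 per cell: chi-squared reference within 0.02 of
        # a 20,000-draw permutation distribution of the same H statistic
        rng = np.random.default_rng(3)
        a = np.repeat(["a1", "a2", "a3"], 16)
        b = np.tile(np.repeat(["b1", "b2"], 8), 3)
        values = rng.standard_normal(48)
        values[a == "a2"] += 0.5
        obs = scheirer_ray_hare(values, a, b)["A"]
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            h = scheirer_ray_hare(rng.permutation(values), a, b)["A"].statistic
            count += h >= obs.statistic
        p_perm = (1 + count) / (1 + n_perm)
        assert obs.p == pytest.approx(p_perm, abs=0.02)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            scheirer_ray_hare(
                np.arange(6.0), ["a", "a", "a", "b", "b", "b"],
                ["x", "x", "x", "x", "x", "y"],
            )


class TestKruskalEta2:
    def test_identical_groups_null(self):
        x = np.arange(10.0)
        res = kruskal_eta2(np.concatenate([x, x]), ["a"] * 10 + ["b"] * 10)
        assert res.statistic < 0.1
        assert res.effect < 0  # eta^2 negative near the null is allowed

    def test_two_groups_match_mann_whitney(self, rng):
        x = rng.standard_normal(40)
        g = np.repeat(["a", "b"], 20)
        x[g == "b"] += 0.7
        res = kruskal_eta2(x, g)
        mw = mann_whitney_effect(x[g == "a"], x[g == "b"], continuity=False)
        assert res.p == pytest.approx(mw.p, abs=1e-6)

    def test_eta2_ci_brackets_estimate(self, rng):
        x = rng.standard_normal(60)
        g = np.repeat(["a", "b", "c"], 20)
        x[g == "c"] += 1.0
        res = kruskal_eta2(x, g, seed=1)
        assert res.ci_low <= res.effect <= res.ci_high


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_effect([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0  # no x exceeds any y

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6) + 0.5
            approx = mann_whitney_effect(x, y).p
            exact = sps.mannwhitneyu(x, y, method="exact").pvalue
            assert approx == pytest.approx(exact, abs=0.02)

    def test_null_effect_size_small(self):
        # under the null E[r] = E|Z|/sqrt(N) ~= 0.8/sqrt(60) ~= 0.10,
        # so the seed-averaged r must sit at or below that small level
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rs.append(
                mann_whitney_effect(
                    rng.standard_normal(30), rng.standard_normal(30), n_boot=10
                ).effect
            )
        assert np.mean(rs) < 0.12

    def test_monotone_invariance(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        r1 = mann_whitney_effect(x, y, n_boot=10)
        r2 = mann_whitney_effect(np.exp(x), np.exp(y), n_boot=10)
        assert r1.statistic == r2.statistic
        assert r1.p == r2.p


class TestTFCE:
    def test_zero_field(self):
        assert np.all(tfce_enhance(np.zeros((8, 8, 8))) == 0)

    def test_uniform_cluster_closed_form(self):
        # single uniform cluster, extent e, height h: as dh -> 0 the TFCE
        # value tends to e^0.5 h^3 / 3
        vol = np.zeros((20, 20, 20))
        vol[4:10, 4:10, 4:10] = 1.5  # e = 216, h = 1.5
        e, h = 216, 1.5
        enh = tfce_enhance(vol, dh=h / 100)
        expect = np.sqrt(e) * h**3 / 3
        assert enh[6, 6, 6] == pytest.approx(expect, rel=0.02)

    def test_extent_doubling_scales_sqrt2(self):
        h = 2.0
        v1 = np.zeros((24, 24, 24))
        v1[2:6, 2:6, 2:6] = h  # 64 voxels
        v2 = np.zeros((24, 24, 24))
        v2[2:10, 2:6, 2:6] = h  # 128 voxels
        e1 = tfce_enhance(v1, dh=h / 200)[3, 3, 3]
        e2 = tfce_enhance(v2, dh=h / 200)[3, 3, 3]
        assert e2 / e1 == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_monotone_in_stat(self, rng):
        base = np.abs(rng.standard_normal((10, 10, 10)))
        bigger = base + 0.5
        dh = bigger.max() / 100
        e1 = tfce_enhance(base, dh=dh)
        e2 = tfce_enhance(bigger, dh=dh)
        assert np.all(e2 >= e1 - 1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tfce_enhance(-np.ones((4, 4, 4)))


def _full_mask(dims):
    return BrainMask(default_grid(dims), np.ones(dims, dtype=bool))


class TestPermutationGLM:
    def test_single_permutation_boundary(self, rng):
        Y = rng.standard_normal((12, 20))
        res = permutation_glm(Y, ["a"] * 6 + ["b"] * 6, n_perm=1, seed=0)
        assert np.all(res.p_fwe >= 0.5)  # (1 + c)/(1 + 1), no division error

    def test_seeded_determinism(self, rng):
        Y = rng.standard_normal((20, 50))
        g = ["a"] * 10 + ["b"] * 10
        r1 = permutation_glm(Y, g, n_perm=100, seed=7)
        r2 = permutation_glm(Y, g, n_perm=100, seed=7)
        assert np.array_equal(r1.p_fwe, r2.p_fwe)
        assert np.array_equal(r1.stat, r2.stat)

    def test_p_monotone_in_stat(self, rng):
        Y = rng.standard_normal((30, 80))
        Y[15:, :10] += 1.0
        res = permutation_glm(Y, ["a"] * 15 + ["b"] * 15, n_perm=200, seed=1)
        order = np.argsort(res.stat)
        p_sorted = res.p_fwe[order]
        assert np.all(np.diff(p_sorted) <= 1e-12)

    def test_planted_blob_detected_with_tfce(self):
        # 1 SD shift in a 64-voxel blob at n = 30/30: most blob voxels
        # reach p_FWE < 0.05 in the majority of seeds
        dims = (12, 12, 12)
        mask = _full_mask(dims)
        blob = np.zeros(dims, dtype=bool)
        blob[4:8, 4:8, 4:8] = True
        blob_vec = mask.extract(blob.astype(float)) > 0.5
        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((60, mask.n_voxels))
            Y[30:, blob_vec] += 1.0
            res = permutation_glm(
                Y, ["a"] * 30 + ["b"] * 30, n_perm=500, seed=seed,
                enhancement="tfce", mask=mask,
            )
            wins += (res.p_fwe[blob_vec] < 0.05).mean() >= 0.8
            assert (res.p_fwe[~blob_vec] < 0.05).mean() < 0.05
        assert wins >= 2

    def test_interaction_permutes_under_main_effects(self, rng):
        # crossed design with strong main effects but no interaction:
        # the interaction test stays null
        n = 40
        g = np.tile(["a", "b"], n // 2)
        d = np.repeat(["d1", "d2"], n // 2)
        Y = (
            rng.standard_normal((n, 30))
            + 2.0 * (g == "b")[:, None]
            + 1.5 * (d == "d2")[:, None]
        )
        res = permutation_glm(Y, g, interaction_with=d, n_perm=300, seed=2)
        assert res.p_fwe.min() > 0.05

    def test_rank_deficient_design_rejected(self, rng):
        Y = rng.standard_normal((10, 5))
        g = ["a"] * 5 + ["b"] * 5
        nuis = (np.asarray(g) == "b").astype(float)  # duplicates the factor
        with pytest.raises(ValueError, match="rank deficient"):
            permutation_glm(Y, g, nuisance=nuis, n_perm=10)


class TestClusters:
    def _result(self, p_fwe, stat, mask):
        from petnorm.stats import StatMapResult

        return StatMapResult(
            stat=stat, p_uncorrected=p_fwe, p_fwe=p_fwe, n_permutations=100,
            enhancement="none", mask=mask,
        )

    def test_empty_when_nothing_significant(self):
        mask = _full_mask((8, 8, 8))
        res = self._result(
            np.ones(mask.n_voxels), np.zeros(mask.n_voxels), mask
        )
        assert len(extract_clusters(res, mask)) == 0

    def test_min_size_threshold(self):
        mask = _full_mask((12, 12, 12))
        sig = np.zeros((12, 12, 12), dtype=bool)
        sig[0:7, 0:7, 0:1] = True      # 49 voxels
        sig[8:12, 8:12, 8:12] = True   # 64 voxels, disjoint
        p = np.where(mask.extract(sig.astype(float)) > 0.5, 0.01, 0.99)
        res = self._result(p, np.ones(mask.n_voxels), mask)
        clusters = extract_clusters(res, mask, min_size=50)
        assert len(clusters) == 1
        assert clusters.clusters[0]["size"] == 64

    def test_cluster_mean_z_arithmetic(self, rng):
        mask = _full_mask((10, 10, 10))
        sig = np.zeros((10, 10, 10), dtype=bool)
        sig[2:7, 2:7, 2:7] = True
        sig_vec = mask.extract(sig.astype(float)) > 0.5
        p = np.where(sig_vec, 0.01, 0.99)
        stat = rng.random(mask.n_voxels)
        Z = rng.standard_normal((4, mask.n_voxels))
        res = self._result(p, stat, mask)
        clusters = extract_clusters(res, mask, min_size=50, Z=Z)
        c = clusters.clusters[0]
        assert np.allclose(
            c["mean_z"], Z[:, sig_vec].mean(axis=1)
        )
        assert c["peak_stat"] == stat[sig_vec].max()


class TestRankInvariance:
    def test_rank_tests_invariant_under_monotone_transform(self, rng):
        values = rng.standard_normal(36)
        a = np.repeat(["a1", "a2"], 18)
        b = np.tile(np.repeat(["b1", "b2"], 9), 2)
        r1 = scheirer_ray_hare(values, a, b)
        r2 = scheirer_ray_hare(np.tanh(values) * 7 + 2, a, b)
        for key in r1:
            assert r1[key].statistic == pytest.approx(r2[key].statistic, abs=1e-12)


class TestSpearmanClinical:
    def test_perfect_and_inverse(self):
        panss = pd.DataFrame({"panss_tot": np.arange(10.0) + 30})
        meas = pd.DataFrame(
            {"same": np.arange(10.0), "neg": -np.arange(10.0)}
        )
        out = spearman_clinical(meas, panss).set_index("measure")
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["neg", "rho"] == pytest.approx(-1.0)

    def test_pairwise_missing_dropped(self):
        panss = pd.DataFrame({"p": [1, 2, np.nan, 4, 5, 6]})
        meas = pd.DataFrame({"m": [1, 2, 3, 4, 5, np.nan]})
        out = spearman_clinical(meas, panss)
        assert out.loc[0, "n"] == 4

    def test_too_few_pairs_skipped(self):
        panss = pd.DataFrame({"p": [1.0, 2.0, np.nan, np.nan, np.nan]})
        meas = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0]})
        assert spearman_clinical(meas, panss).empty
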