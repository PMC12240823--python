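"""Harmonization: kernel conversion/smoothing, ComBat EB model, residual tests."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from petnorm import (
    CombatHarmonizer,
    GeneratorSpec,
    ParametricMapSet,
    apply_combat,
    fit_combat,
    fwhm_to_sigma,
    gaussian_smooth,
    generate_cohort,
    make_brain_mask,
    residual_scanner_effect,
    select_smoothing_kernel,
)
from petnorm.simulate import default_grid
from petnorm.imaging import BrainMask

DATA = Path(__file__).parent / "data"


class TestKernelConversion:
    def test_closed_form(self):
        assert fwhm_to_sigma(2.0 * np.sqrt(2.0 * np.log(2.0))) == pytest.approx(1.0)
        assert fwhm_to_sigma(2.3548) == pytest.approx(1.0, abs=1e-4)

    def test_ratio_is_2_35_to_3sf(self):
        ratio = 5.0 / fwhm_to_sigma(5.0)
        assert float(f"{ratio:.3g}") == 2.35

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            fwhm_to_sigma(bad)


def _map_set(values, grid=None, mask=None):
    grid = grid or default_grid((16, 16, 16))
    mask = mask or make_brain_mask(grid)
    values = np.atleast_2d(values)
    ids = [f"s{i}" for i in range(values.shape[0])]
    return ParametricMapSet(ids, values, mask)


class TestGaussianSmoothing:
    def test_constant_field_unchanged(self):
        ms = _map_set(np.full(16**3, 3.7))
        out = gaussian_smooth(ms, fwhm=5.0)
        assert np.allclose(out.values, 3.7, atol=1e-10)

    def test_fwhm_zero_is_identity(self, rng):
        ms = _map_set(rng.standard_normal(16**3))
        out = gaussian_smooth(ms, 0.0)
        assert np.array_equal(out.values, ms.values)

    def test_impulse_matches_analytic_kernel(self):
        grid = default_grid((21, 21, 21))
        mask = make_brain_mask(grid)
        vec = np.zeros(mask.n_voxels)
        centre_vol = np.zeros(grid.dims)
        centre_vol[10, 10, 10] = 1.0
        ms = _map_set(mask.extract(centre_vol), grid, mask)
        fwhm = 4.0  # mm
        out = gaussian_smooth(ms, fwhm)
        vol = mask.insert(out.values[0])
        sigma_vox = fwhm_to_sigma(fwhm) / 2.0  # 2 mm voxels
        for offset in [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 2)]:
            d2 = sum(o**2 for o in offset)
            expect = np.exp(-d2 / (2 * sigma_vox**2)) / (
                (2 * np.pi) ** 1.5 * sigma_vox**3
            )
            got = vol[10 + offset[0], 10 + offset[1], 10 + offset[2]]
            assert got == pytest.approx(expect, rel=2e-3, abs=1e-6)

    def test_total_sum_preserved_under_full_mask(self, rng):
        ms = _map_set(rng.random(16**3))
        out = gaussian_smooth(ms, 6.0)
        assert out.values.sum() == pytest.approx(ms.values.sum(), rel=1e-6)


class TestKernelSelection:
    def test_identical_data_chooses_zero(self, rng):
        ms = _map_set(rng.standard_normal(16**3))
        choice = select_smoothing_kernel(ms, ms, [0.0, 3.0, 6.0])
        assert choice.sigma_mm == 0.0

    def test_self_consistency_recovers_kernel(self, rng):
        target = _map_set(rng.standard_normal((4, 16**3)))
        reference = gaussian_smooth(target, 3.0)
        choice = select_smoothing_kernel(target, reference, [0.0, 1.5, 3.0, 4.5])
        assert choice.sigma_mm == 3.0

    def test_chosen_in_candidates_and_empty_rejected(self, rng):
        ms = _map_set(rng.standard_normal(16**3))
        choice = select_smoothing_kernel(ms, ms, [1.5, 3.0])
        assert choice.sigma_mm in choice.candidates
        with pytest.raises(ValueError):
            select_smoothing_kernel(ms, ms, [])


def _two_batch_data(n=20, v=60, shift=0.7, scale=1.0, noise=1.0, seed=0,
                    slope=0.0):
    rng = np.random.default_rng(seed)
    batch = np.array(["A"] * n + ["B"] * n)
    age = rng.uniform(20, 60, 2 * n)
    Y = (
        5.0
        + slope * (age - 40.0)[:, None]
        + np.where((batch == "B")[:, None], shift, 0.0)
        + rng.standard_normal((2 * n, v))
        * noise
        * np.where((batch == "B")[:, None], scale, 1.0)
    )
    cov = pd.DataFrame({"age": age})
    return Y, batch, cov


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        Y = rng.standard_normal((10, 30))
        m = CombatHarmonizer().fit(Y, batch=["A"] * 10)
        out = m.transform(Y, batch=["A"] * 10)
        assert np.allclose(out, Y, atol=1e-8)

    def test_noiseless_additive_shift_recovered(self):
        # two batches, pure additive shift, no noise: the gamma* difference
        # must recover the shift up to centering
        v = 25
        base = np.tile(np.linspace(4, 6, v), (12, 1))
        # subject variation, balanced within each batch so batches differ
        # by exactly delta
        base += np.tile(np.linspace(-0.1, 0.1, 6), 2)[:, None]
        delta = 0.8
        Y = base.copy()
        Y[6:] += delta
        batch = np.array(["A"] * 6 + ["B"] * 6)
        m = CombatHarmonizer().fit(Y, batch=batch)
        sd = np.sqrt(m.pooled_var_)
        gdiff = (m.gamma_star_[1] - m.gamma_star_[0]) * sd
        assert np.allclose(gdiff, delta, atol=1e-6)

    def test_matches_reference_implementation_fixture(self):
        Y = pd.read_csv(DATA / "combat_input_values.csv").to_numpy()
        cov = pd.read_csv(DATA / "combat_input_covariates.csv")
        ref = pd.read_csv(DATA / "combat_reference_output.csv").to_numpy()
        m = CombatHarmonizer(covariate_names=("age", "sex")).fit(
            Y, batch=cov["batch"], covariates=cov[["age", "sex"]]
        )
        adj = m.transform(Y, batch=cov["batch"], covariates=cov[["age", "sex"]])
        assert np.abs(adj - ref).max() < 1e-5

    def test_refit_on_adjusted_data_is_null(self):
        # idempotence: with voxel-heterogeneous batch shifts (weak EB
        # shrinkage) a second fit finds essentially no batch effect left
        rng = np.random.default_rng(3)
        n, v = 400, 60
        Y = 5 + rng.standard_normal((2 * n, v))
        Y[n:] += rng.normal(0.5, 1.0, v)
        batch = np.array(["A"] * n + ["B"] * n)
        m = CombatHarmonizer().fit(Y, batch=batch)
        adj = m.transform(Y, batch=batch)
        m2 = CombatHarmonizer().fit(adj, batch=batch)
        assert np.abs(m2.gamma_star_).max() < 1e-3

    def test_covariate_slope_preserved(self):
        slope = 0.05
        Y, batch, cov = _two_batch_data(
            n=40, v=40, shift=0.8, noise=0.3, seed=4, slope=slope
        )
        m = CombatHarmonizer(covariate_names=("age",)).fit(
            Y, batch=batch, covariates=cov
        )
        adj = m.transform(Y, batch=batch, covariates=cov)
        X = np.column_stack([np.ones(len(cov)), cov["age"] - 40.0])
        beta = np.linalg.lstsq(X, adj, rcond=None)[0][1]
        resid = adj - X @ np.linalg.lstsq(X, adj, rcond=None)[0]
        se = np.sqrt(
            resid.var(axis=0, ddof=2)
            / ((cov["age"] - cov["age"].mean()) ** 2).sum()
        )
        covered = np.abs(beta - slope) < 1.96 * se
        assert covered.mean() > 0.85  # ~95% nominal coverage per voxel

    def test_unseen_batch_rejected(self):
        Y, batch, _ = _two_batch_data()
        m = CombatHarmonizer().fit(Y, batch=batch)
        with pytest.raises(ValueError, match="unseen batch"):
            m.transform(Y[:4], batch=["C"] * 4)

    def test_rank_deficient_design_rejected(self):
        Y, batch, _ = _two_batch_data()
        bad_cov = (batch == "B").astype(float)  # collinear with batch columns
        with pytest.raises(ValueError, match="rank deficient"):
            CombatHarmonizer().fit(Y, batch=batch, covariates=bad_cov)

    def test_json_round_trip(self, tmp_path):
        Y, batch, cov = _two_batch_data(seed=6)
        m = CombatHarmonizer(covariate_names=("age",)).fit(
            Y, batch=batch, covariates=cov
        )
        m.to_json(tmp_path / "combat.json")
        m2 = CombatHarmonizer.from_json(tmp_path / "combat.json")
        a1 = m.transform(Y, batch=batch, covariates=cov)
        a2 = m2.transform(Y, batch=batch, covariates=cov)
        assert np.array_equal(a1, a2)

    def test_batch_variance_reduced(self):
        # between-batch variance of voxel means shrinks by >= 90% on a
        # planted-shift simulation
        reductions = []
        for seed in range(5):
            Y, batch, _ = _two_batch_data(n=20, shift=1.0, seed=seed)
            m = CombatHarmonizer().fit(Y, batch=batch)
            adj = m.transform(Y, batch=batch)

            def between_var(M):
                means = np.stack(
                    [M[batch == b].mean(axis=0) for b in ("A", "B")]
                )
                return means.var(axis=0).mean()

            reductions.append(1 - between_var(adj) / between_var(Y))
        assert np.mean(reductions) >= 0.90


class TestPatientApplication:
    def test_planted_deviation_preserved(self, atlas16):
        # HC-fitted model applied to patients: the planted striatal
        # deviation must survive harmonization (< 5% relative change)
        spec = GeneratorSpec(
            n_subjects={
                ("scannerA", "HC"): 25,
                ("scannerB", "HC"): 25,
                ("scannerA", "FEP"): 20,
                ("scannerB", "FEP"): 20,
            },
            seed=13,
        )
        maps, cohort = generate_cohort(spec)
        hc = (cohort["group"] == "HC").to_numpy()
        batch = cohort["scanner_id"].to_numpy()
        cov = cohort[["age", "sex"]]
        model = fit_combat(
            maps.subset(np.flatnonzero(hc)), batch[hc], cov[hc],
            covariate_names=("age", "sex"),
        )
        harm = apply_combat(model, maps, batch, cov)
        striatum = atlas16.region_mask(1, maps.mask)
        before = (
            maps.values[~hc][:, striatum].mean()
            - maps.values[hc][:, striatum].mean()
        )
        after = (
            harm.values[~hc][:, striatum].mean()
            - harm.values[hc][:, striatum].mean()
        )
        assert after == pytest.approx(before, rel=0.05)


class TestResidualScannerEffect:
    def test_identical_batches_null(self, rng):
        Y = rng.standard_normal((30, 50))
        Y2 = np.vstack([Y, Y])  # batch B literally duplicates batch A
        batch = ["A"] * 30 + ["B"] * 30
        report = residual_scanner_effect(Y2, batch)
        assert report["mean"].p > 0.9
        assert report["mean"].effect < 0.05

    def test_planted_shift_detected_and_removed(self):
        detected, removed = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            Y, batch, _ = _two_batch_data(n=25, v=80, shift=0.6, seed=seed)
            rep = residual_scanner_effect(Y, batch)
            if rep["mean"].p < 0.01:
                detected += 1
            m = CombatHarmonizer().fit(Y, batch=batch)
            rep2 = residual_scanner_effect(m.transform(Y, batch=batch), batch)
            if rep2["mean"].p >= 0.05:
                removed += 1
        assert detected == n_seeds
        assert removed >= 0.9 * n_seeds

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="2 batches"):
            residual_scanner_effect(rng.standard_normal((8, 5)), ["A"] * 8)


class TestSmoothingCannotFixShifts:
    def test_additive_shift_survives_smoothing(self):
        # constant-plus-shift phantom: smoothing leaves the between-batch
        # mean difference exactly in place
        grid = default_grid((12, 12, 12))
        mask = make_brain_mask(grid)
        base = np.full(mask.n_voxels, 2.0)
        ms = ParametricMapSet(
            ["a0", "a1", "b0", "b1"],
            np.vstack([base, base, base + 0.5, base + 0.5]),
            mask,
        )
        out = gaussian_smooth(ms, 6.0)
        mean_a = out.values[:2].mean()
        mean_b = out.values[2:].mean()
        assert mean_b - mean_a == pytest.approx(0.5, abs=1e-9)
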