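"""Canned simulation experiments used for validation and reporting.

These functions wire the generator, harmonization and normative model into
the standard study designs the package is validated on — most importantly
the null-calibration design: fit normative models on a harmonized
two-scanner reference cohort, score held-out subjects drawn from the same
generative law, and measure the per-subject extreme-deviation fractions,
which for a calibrated Gaussian model should sit at the ~2.5% / ~5%
chance levels.
"""

from __future__ import annotations

import numpy as np

from .harmonize import apply_combat, fit_combat
from .normative import NormativeBLR
from .simulate import GeneratorSpec, generate_cohort

__all__ = ["null_calibration"]


def null_calibration(
    seed: int,
    dims: tuple[int, int, int] = (16, 16, 16),
    n_ref: int = 200,
    n_test: int = 100,
    z_threshold: float = 2.0,
) -> dict[str, float]:
    """Chance-level calibration of held-out null subjects.

    Generates a two-scanner reference cohort of ``n_ref`` healthy controls
    (linear age and sex effects, Gaussian noise, scanner location/scale
    batch effects), ComBat-harmonizes it, fits one Bayesian linear
    regression per voxel, then draws ``n_test`` fresh subjects from the
    identical generative distribution, harmonizes them with the stored
    model and scores them.  Returns the across-subject averages of the
    per-subject percentages of voxels with Z > t, Z < -t and |Z| > t.
    """
    seed = int(seed)
    n_a = int(round(n_ref * 0.6))
    ref_spec = GeneratorSpec(
        dims=dims,
        n_subjects={("scannerA", "HC"): n_a, ("scannerB", "HC"): n_ref - n_a},
        seed=seed,
    )
    maps, cohort = generate_cohort(ref_spec)
    combat = fit_combat(
        maps,
        cohort["scanner_id"],
        covariates=cohort[["age", "sex"]],
        covariate_names=("age", "sex"),
    )
    harm = apply_combat(combat, maps, cohort["scanner_id"], cohort[["age", "sex"]])
    model = NormativeBLR(covariates=("age", "sex")).fit(cohort, harm.values)

    m_a = int(round(n_test * 0.6))
    test_spec = GeneratorSpec(
        dims=dims,
        n_subjects={("scannerA", "HC"): m_a, ("scannerB", "HC"): n_test - m_a},
        seed=seed + 1,
    )
    maps_t, cohort_t = generate_cohort(test_spec)
    harm_t = apply_combat(
        combat, maps_t, cohort_t["scanner_id"], cohort_t[["age", "sex"]]
    )
    Z = model.predict_z(cohort_t, harm_t.values)
    valid = np.isfinite(Z)
    denom = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        zz = np.where(valid, Z, 0.0)
        pos = 100.0 * ((zz > z_threshold) & valid).sum(axis=1) / denom
        neg = 100.0 * ((zz < -z_threshold) & valid).sum(axis=1) / denom
        tot = pos + neg
    return {
        "mean_pct_pos": float(pos.mean()),
        "mean_pct_neg": float(neg.mean()),
        "mean_pct_tot": float(tot.mean()),
        "n_test": int(n_test),
        "n_voxels": int(Z.shape[1]),
    }
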