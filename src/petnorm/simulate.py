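"""Synthetic multi-scanner PET cohort generator.

Emulates the statistical structure that voxel-wise normative modelling of
parametric dopamine maps assumes: a smooth baseline field with elevated
striatal uptake, linear age/sex(/BMI) covariate effects, per-scanner additive
and multiplicative batch effects, spatially structured deviation fields in
patient groups (positive striatal for first-episode psychosis, negative
cortical for chronic schizophrenia), symptom scores coupled to deviation
magnitude, and treatment-response labels driven by striatal deviation.

The generative model for subject s at voxel v is

    y_sv = mu_v + a_v (age_s - 40) + s_v sex_s + b_v (bmi_s - 25)
           + g_{i(s),v} + theta_s D_{g(s),v} + d_{i(s)} sigma_v eps_sv

with eps_sv ~ N(0, 1), theta_s = 0 for controls and
theta_s ~ N(theta_mean_g, theta_sd_g^2) for patients.  Values are on a
dopamine-synthesis Ki-like scale (min^-1, baseline ~0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging import (
    AtlasParcellation,
    BrainMask,
    ParametricMapSet,
    VoxelGrid,
)

__all__ = [
    "GeneratorSpec",
    "default_grid",
    "make_brain_mask",
    "make_toy_atlas",
    "generate_cohort",
]

GROUPS = ("HC", "FEP", "SCZ")


def default_grid(dims: tuple[int, int, int] = (16, 16, 16)) -> VoxelGrid:
    """Desk-scale grid: 2 mm isotropic voxels, scanner-style affine."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -np.asarray(dims) * 1.0  # centre the grid at the origin
    return VoxelGrid(tuple(dims), affine)


def _radial(dims: tuple[int, int, int]) -> np.ndarray:
    """Normalized distance from grid centre (1.0 at the nearest face)."""
    axes = [np.arange(d) - (d - 1) / 2.0 for d in dims]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    half = np.asarray(dims) / 2.0
    return np.sqrt((xx / half[0]) ** 2 + (yy / half[1]) ** 2 + (zz / half[2]) ** 2)


def make_brain_mask(grid: VoxelGrid, fraction: float = 1.0) -> BrainMask:
    """Full-grid mask by default; ``fraction < 1`` keeps a central ellipsoid."""
    if fraction >= 1.0:
        flags = np.ones(grid.dims, dtype=bool)
    else:
        flags = _radial(grid.dims) <= fraction
    return BrainMask(grid, flags)


def make_toy_atlas(grid: VoxelGrid) -> AtlasParcellation:
    """Two-region desk atlas: central "striatum" ellipsoid + "cortex" shell.

    The striatum contains at least 50 voxels (the cluster-reporting
    convention), the two regions are disjoint, and label 0 is background.
    """
    if any(d < 8 for d in grid.dims):
        raise ValueError(f"grid too small for toy atlas (need ≥ 8 per axis): {grid.dims}")
    r = _radial(grid.dims)
    striatum = r <= 0.30
    if striatum.sum() < 50:  # tiny grids: widen until the ellipsoid is reportable
        striatum = r <= 0.40
    cortex = (r > 0.55) & (r <= 0.85)
    labels = np.zeros(grid.dims, dtype=np.int32)
    labels[cortex] = 2
    labels[striatum] = 1
    if (labels == 1).sum() < 50:
        raise ValueError("grid too small: striatum region has fewer than 50 voxels")
    return AtlasParcellation(grid, labels, {1: "striatum", 2: "cortex"})


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic cohort.

    ``n_subjects`` maps (scanner_id, group) → count.  Defaults follow the
    recommended reference design for multi-scanner PET normative models:
    ~50 reference scans split over scanners with at least 10 controls each.
    Effect sizes are on the Ki scale (baseline 1.0e-2 min^-1, noise SD
    1.0e-3): the age slope alone explains ~10% of between-subject variance,
    matching the modest explained variance typical of voxel-wise PET models.
    """

    dims: tuple[int, int, int] = (16, 16, 16)
    n_subjects: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {("scannerA", "HC"): 30, ("scannerB", "HC"): 20}
    )
    baseline: float = 1.0e-2           # mu_v outside striatum (Ki, min^-1)
    striatal_boost: float = 4.0e-3     # added to mu_v inside the striatum
    age_slope: float = -3.0e-5         # a_v, per year
    sex_offset: float = 5.0e-4         # s_v, added for sex == 1
    bmi_slope: float = 0.0             # b_v, per kg/m^2 (0 = BMI unused)
    noise_sd: float = 1.0e-3           # sigma_v
    batch_shift: Mapping[str, float] = field(
        default_factory=lambda: {"scannerA": 0.0, "scannerB": 8.0e-4}
    )
    batch_scale: Mapping[str, float] = field(
        default_factory=lambda: {"scannerA": 1.0, "scannerB": 1.25}
    )
    # patient deviation magnitudes, in absolute Ki units (noise_sd units ≈ Z)
    theta_mean: Mapping[str, float] = field(
        default_factory=lambda: {"FEP": 2.5e-3, "SCZ": 2.0e-3}
    )
    theta_sd: Mapping[str, float] = field(
        default_factory=lambda: {"FEP": 1.0e-3, "SCZ": 8.0e-4}
    )
    response_cutoff: float = 2.5e-3    # striatal-mean deviation threshold
    label_noise: float = 0.1           # flip probability epsilon
    age_range: tuple[float, float] = (20.0, 65.0)
    with_bmi: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(d <= 0 for d in self.batch_scale.values()):
            raise ValueError("batch scale factors must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        scanners = {sc for sc, _ in self.n_subjects}
        for sc in scanners:
            if self.n_subjects.get((sc, "HC"), 0) < 1:
                raise ValueError(
                    f"scanner {sc!r} has no healthy controls; batch effects "
                    "would not be estimable for harmonization"
                )
        for _, g in self.n_subjects:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")


def _deviation_template(
    group: str, atlas: AtlasParcellation, mask: BrainMask
) -> np.ndarray:
    """Unit-magnitude spatial deviation field D_g over masked voxels."""
    n = mask.n_voxels
    if group == "HC":
        return np.zeros(n)
    striatum = atlas.region_mask(1, mask)
    cortex = atlas.region_mask(2, mask)
    D = np.zeros(n)
    if group == "FEP":  # elevated dopamine-synthesis deviation, striatal
        D[striatum] = 1.0
    elif group == "SCZ":  # chronic pattern: striatal elevation + cortical deficit
        D[striatum] = 1.0
        D[cortex] = -0.75
    return D


def _panss(rng: np.random.Generator, theta_units: np.ndarray) -> pd.DataFrame:
    """PANSS scores increasing in deviation magnitude (theta in noise-SD units).

    Total = 30 + round(positive part of a linear function of theta + noise),
    split 30/25/45% into positive/negative/general subscales so that the
    subscale identity panss_tot = pos + neg + gen holds exactly.
    """
    raw = 25.0 + 6.0 * theta_units + rng.normal(0.0, 8.0, size=theta_units.shape)
    extra = np.round(np.clip(raw, 0.0, 150.0)).astype(int)
    pos = np.round(extra * 0.30).astype(int)
    neg = np.round(extra * 0.25).astype(int)
    gen = extra - pos - neg
    return pd.DataFrame(
        {
            "panss_pos": 7 + pos,   # each subscale has a floor (7/7/16 items × 1)
            "panss_neg": 7 + neg,
            "panss_gen": 16 + gen,
            "panss_tot": 30 + extra,
        }
    )


def generate_cohort(
    spec: GeneratorSpec,
    mask: BrainMask | None = None,
    atlas: AtlasParcellation | None = None,
) -> tuple[ParametricMapSet, pd.DataFrame]:
    """Draw one cohort of parametric maps plus its covariate table.

    Identical spec + seed → bitwise-identical output.  Returns the map set
    (subjects × masked voxels, Ki-like units) and a cohort table with columns
    subject_id, age, sex, (bmi,) scanner_id, dataset_id, group, response,
    theta, panss_* (patients only; NaN for controls).
    """
    spec.validate()
    grid = default_grid(spec.dims)
    if mask is None:
        mask = make_brain_mask(grid)
    if atlas is None:
        atlas = make_toy_atlas(grid)
    rng = np.random.default_rng(spec.seed)
    nv = mask.n_voxels

    striatum = atlas.region_mask(1, mask)
    mu = np.full(nv, spec.baseline)
    mu[striatum] += spec.striatal_boost

    templates = {g: _deviation_template(g, atlas, mask) for g in GROUPS}

    rows: list[dict] = []
    values = []
    idx = 0
    # deterministic ordering of the (scanner, group) cells
    for (scanner, group) in sorted(spec.n_subjects):
        n = int(spec.n_subjects[(scanner, group)])
        for _ in range(n):
            sid = f"{scanner}_{group}_{idx:04d}"
            age = rng.uniform(*spec.age_range)
            sex = int(rng.integers(0, 2))
            bmi = float(rng.normal(25.0, 3.5)) if spec.with_bmi else np.nan
            theta = (
                0.0
                if group == "HC"
                else float(
                    rng.normal(spec.theta_mean[group], spec.theta_sd[group])
                )
            )
            eps = rng.standard_normal(nv)
            y = (
                mu
                + spec.age_slope * (age - 40.0)
                + spec.sex_offset * sex
                + (spec.bmi_slope * (bmi - 25.0) if spec.with_bmi else 0.0)
                + spec.batch_shift.get(scanner, 0.0)
                + theta * templates[group]
                + spec.batch_scale.get(scanner, 1.0) * spec.noise_sd * eps
            )
            values.append(y)
            rows.append(
                dict(
                    subject_id=sid,
                    age=age,
                    sex=sex,
                    bmi=bmi,
                    scanner_id=scanner,
                    dataset_id=f"ds_{scanner}",  # case-control dataset per scanner
                    group=group,
                    theta=theta,
                )
            )
            idx += 1

    cohort = pd.DataFrame(rows)
    maps = ParametricMapSet(
        cohort["subject_id"].tolist(), np.vstack(values), mask, tracer_tag="Ki"
    )

    # response labels: responder iff striatal mean deviation exceeds the
    # cutoff, then flipped with probability label_noise
    patient = cohort["group"] != "HC"
    striatal_dev = np.array(
        [
            row["theta"] * templates[row["group"]][striatum].mean()
            for row in rows
        ]
    )
    responder = striatal_dev > spec.response_cutoff
    flip = rng.random(len(cohort)) < spec.label_noise
    responder = responder ^ flip
    response = np.where(responder, "responder", "nonresponder")
    cohort["response"] = np.where(patient, response, "unknown")

    # PANSS for patients only, coupled to deviation magnitude
    panss = _panss(rng, cohort["theta"].to_numpy() / spec.noise_sd)
    for col in panss.columns:
        cohort[col] = np.where(patient, panss[col], np.nan)

    if not spec.with_bmi:
        cohort = cohort.drop(columns=["bmi"])
    return maps, cohort
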