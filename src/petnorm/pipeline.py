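"""End-to-end analysis pipeline with serialized, restart-safe artifacts.

Stage order: simulate → harmonize → fit-nm → deviate → stats → classify.
Each stage communicates with the next only through files in the run
directory, so any stage can be re-run from its predecessors' artifacts.
Healthy controls are scored with k-fold cross-validation; patients are
scored with the full reference-fitted model.  A master seed
deterministically derives per-stage seeds, and a manifest records the
config hash, seed and artifact checksums so a re-run can be verified to be
bitwise identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deviations as dev
from . import stats as st
from .classify import auc_ci, delong_compare, roc_auc
from .harmonize import (
    CombatHarmonizer,
    apply_combat,
    fit_combat,
    gaussian_smooth,
    residual_scanner_effect,
    select_smoothing_kernel,
)
from .imaging import ParametricMapSet, make_probability_mask, read_map_set, write_map
from .normative import NormativeBLR, crossval_deviations
from .simulate import GeneratorSpec, default_grid, generate_cohort, make_toy_atlas

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """One-file configuration for a full synthetic-scenario run."""

    out_dir: str = "petnorm_run"
    seed: int = 0
    # simulate
    dims: tuple[int, int, int] = (16, 16, 16)
    cohorts: dict = field(
        default_factory=lambda: {
            "scannerA": {"HC": 30, "FEP": 18},
            "scannerB": {"HC": 20, "SCZ": 18},
        }
    )
    # harmonization
    harmonization_method: str = "combat"  # combat | smoothing | none
    harmonization_covariates: tuple[str, ...] = ("age", "sex")
    batch_column: str = "scanner_id"
    smoothing_candidates: tuple[float, ...] = (0.0, 1.5, 3.0, 4.5, 6.0)
    # normative model
    nm_covariates: tuple[str, ...] = ("age", "sex")
    kfold: int = 5
    expv_threshold: float = 0.0
    # deviation metrics / stats
    z_threshold: float = 2.0
    n_perm: int = 200
    alpha: float = 0.05
    min_cluster: int = 50
    tfce: bool = True
    # classification
    scores: tuple[str, ...] = (
        "striatal_mean_z",
        "mean_z",
        "pct_pos",
        "pct_neg",
        "pct_tot",
        "striatal_ki",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.dims = tuple(cfg.dims)
        for name in ("harmonization_covariates", "nm_covariates",
                     "smoothing_candidates", "scores"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _read_cohort(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(_out(cfg) / "cohort.csv")


def _mask_atlas(cfg: PipelineConfig):
    out = _out(cfg)
    mask = make_probability_mask(out / "gm_prob.nii.gz", 0.30)
    import nibabel as nib

    atlas_img = nib.load(str(out / "atlas.nii.gz"))
    from .imaging import AtlasParcellation, VoxelGrid

    labels = np.asarray(atlas_img.get_fdata()).round().astype(int)
    names = json.loads((out / "atlas_names.json").read_text())
    atlas = AtlasParcellation(
        mask.grid, labels, {int(k): v for k, v in names.items()}
    )
    return mask, atlas


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    n_subjects = {
        (sc, grp): n
        for sc, groups in cfg.cohorts.items()
        for grp, n in groups.items()
    }
    spec = GeneratorSpec(
        dims=cfg.dims, n_subjects=n_subjects, seed=cfg.stage_seed("simulate")
    )
    maps, cohort = generate_cohort(spec)
    grid = maps.mask.grid
    atlas = make_toy_atlas(grid)

    write_map(np.ones(grid.dims), out / "gm_prob.nii.gz", grid=grid)
    write_map(atlas.labels.astype(float), out / "atlas.nii.gz", grid=grid)
    (out / "atlas_names.json").write_text(
        json.dumps({str(k): v for k, v in atlas.names.items()})
    )
    maps_dir = out / "maps"
    for i, sid in enumerate(maps.subject_ids):
        write_map(maps.values[i], maps_dir / f"{sid}.nii.gz", mask=maps.mask)
    cohort.to_csv(out / "cohort.csv", index=False)
    echo = cfg.to_dict() | {"generator_seed": spec.seed}
    echo.pop("out_dir")  # location is not part of the scenario
    (out / "spec_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))


def stage_harmonize(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort = _read_cohort(cfg)
    mask, _ = _mask_atlas(cfg)
    paths = [out / "maps" / f"{sid}.nii.gz" for sid in cohort["subject_id"]]
    maps = read_map_set(paths, mask, subject_ids=cohort["subject_id"].tolist())
    batch = cohort[cfg.batch_column].to_numpy()
    hc = (cohort["group"] == "HC").to_numpy()

    if cfg.harmonization_method == "combat":
        cov = cohort[list(cfg.harmonization_covariates)]
        model = fit_combat(
            maps.subset(np.flatnonzero(hc)),
            batch[hc],
            covariates=cov[hc],
            covariate_names=cfg.harmonization_covariates,
        )
        model.to_json(out / "combat_model.json")
        harmonized = apply_combat(model, maps, batch, covariates=cov)
    elif cfg.harmonization_method == "smoothing":
        batches = pd.unique(batch[hc])
        ref_b = batches[0]
        choice = select_smoothing_kernel(
            maps.subset(np.flatnonzero(hc & (batch != ref_b))),
            maps.subset(np.flatnonzero(hc & (batch == ref_b))),
            cfg.smoothing_candidates,
        )
        (out / "smoothing_choice.json").write_text(
            json.dumps(dataclasses.asdict(choice))
        )
        target = batch != ref_b
        smoothed = gaussian_smooth(
            maps.subset(np.flatnonzero(target)), choice.sigma_mm
        )
        values = maps.values.copy()
        values[target] = smoothed.values
        harmonized = ParametricMapSet(
            maps.subject_ids, values, maps.mask, maps.tracer_tag
        )
    elif cfg.harmonization_method == "none":
        harmonized = maps
    else:
        raise ValueError(f"unknown harmonization method {cfg.harmonization_method!r}")

    np.save(out / "harmonized.npy", harmonized.values)
    report = residual_scanner_effect(harmonized.values[hc], batch[hc])
    pd.DataFrame([r.as_row() for r in report.values()]).to_csv(
        out / "scanner_effect_report.csv", index=False
    )


def stage_fit_nm(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort = _read_cohort(cfg)
    mask, _ = _mask_atlas(cfg)
    Y = np.load(out / "harmonized.npy")
    hc = (cohort["group"] == "HC").to_numpy()

    model = NormativeBLR(covariates=cfg.nm_covariates).fit(cohort[hc], Y[hc])
    cv_maps, expv = crossval_deviations(
        Y[hc], cohort[hc], cfg.nm_covariates, k=cfg.kfold,
        seed=cfg.stage_seed("fit-nm"),
    )
    model.expv_ = expv
    model.to_json(out / "nm_model.json")

    Z = np.full_like(Y, np.nan)
    Z[hc] = cv_maps.Z
    if (~hc).any():
        Z[~hc] = model.predict_z(cohort[~hc], Y[~hc])
    np.save(out / "zmaps.npy", Z)
    analysis = (
        model.converged_
        & np.isfinite(expv)
        & (expv > cfg.expv_threshold if cfg.expv_threshold < 0.10
           else expv >= cfg.expv_threshold)
    )
    np.save(out / "analysis_voxels.npy", analysis)
    write_map(
        np.where(np.isfinite(expv), expv, -1.0), out / "expv.nii.gz", mask=mask
    )


def stage_deviate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort = _read_cohort(cfg)
    mask, atlas = _mask_atlas(cfg)
    Z = np.load(out / "zmaps.npy")
    analysis = np.load(out / "analysis_voxels.npy")
    Zm = np.where(analysis[None, :], Z, np.nan)
    hc = (cohort["group"] == "HC").to_numpy()
    ids = cohort["subject_id"].tolist()

    summ_global = dev.summary_measures(Zm, ids, z_threshold=cfg.z_threshold)
    regional = dev.regional_summary(
        Zm, atlas, mask, subject_ids=ids, z_threshold=cfg.z_threshold
    )
    pd.concat([summ_global, regional], ignore_index=True).to_csv(
        out / "summary_measures.csv", index=False
    )

    for grp_name, rows in (("hc", hc), ("patients", ~hc)):
        if not rows.any():
            continue
        for sign in ("pos", "neg", "tot"):
            ov = dev.overlap_map(Zm[rows], sign, cfg.z_threshold)
            write_map(
                np.nan_to_num(ov), out / f"overlap_{grp_name}_{sign}.nii.gz",
                mask=mask,
            )

    rr_rows = []
    if (~hc).any():
        for sign in ("pos", "neg", "tot"):
            r = dev.risk_ratio(Zm[~hc], Zm[hc], sign, cfg.z_threshold)
            rr_rows.append(
                dict(sign=sign, rr=r.rr, ci_low=r.ci_low, ci_high=r.ci_high,
                     a=r.a, b=r.b, c=r.c, d=r.d,
                     continuity_corrected=r.continuity_corrected)
            )
    pd.DataFrame(rr_rows).to_csv(out / "risk_ratios.csv", index=False)


def stage_stats(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort = _read_cohort(cfg)
    mask, _ = _mask_atlas(cfg)
    Z = np.load(out / "zmaps.npy")
    analysis = np.load(out / "analysis_voxels.npy")
    summ = pd.read_csv(out / "summary_measures.csv")
    summ = summ[summ["scope"] == "whole"].set_index("subject_id")
    summ = summ.loc[cohort["subject_id"]]

    rows = []
    is_patient = np.where(cohort["group"] == "HC", "HC", "patient")
    # factorial test needs case-control datasets: keep those with both levels
    both = [
        ds for ds, sub in cohort.groupby("dataset_id")
        if sub["group"].eq("HC").any() and sub["group"].ne("HC").any()
    ]
    keep = cohort["dataset_id"].isin(both).to_numpy()
    if keep.any() and len(both) >= 1 and len(np.unique(is_patient[keep])) == 2:
        for measure in ("mean_z", "pct_pos", "pct_neg", "pct_tot"):
            srh = st.scheirer_ray_hare(
                summ[measure].to_numpy()[keep], is_patient[keep],
                cohort.loc[keep, "dataset_id"],
            )
            for key, res in srh.items():
                rows.append(res.as_row() | {"measure": measure, "term": key})
    pd.DataFrame(rows).to_csv(out / "summary_tests.csv", index=False)

    # voxel-wise permutation GLM, group factor, within analysis voxels
    sel = analysis & np.all(np.isfinite(Z), axis=0)
    from .imaging import BrainMask

    sub_mask = BrainMask(mask.grid, mask.insert(sel.astype(float)) > 0.5)
    result = st.permutation_glm(
        Z[:, sel],
        is_patient,
        n_perm=cfg.n_perm,
        seed=cfg.stage_seed("stats"),
        enhancement="tfce" if cfg.tfce else "none",
        mask=sub_mask,
    )
    write_map(result.stat, out / "fstat.nii.gz", mask=sub_mask)
    write_map(1.0 - result.p_fwe, out / "one_minus_pfwe.nii.gz", mask=sub_mask)
    clusters = st.extract_clusters(
        result, sub_mask, alpha=cfg.alpha, min_size=cfg.min_cluster, Z=Z[:, sel]
    )
    clusters.table().to_csv(out / "clusters.csv", index=False)

    # clinical correlations in patients with PANSS
    pat = cohort["group"] != "HC"
    if pat.any() and "panss_tot" in cohort.columns:
        measures = summ.loc[cohort.loc[pat, "subject_id"],
                            ["mean_z", "pct_pos", "pct_neg", "pct_tot"]]
        clinical = cohort.loc[pat, ["panss_pos", "panss_neg", "panss_gen",
                                    "panss_tot"]]
        measures = measures.reset_index(drop=True)
        clinical = clinical.reset_index(drop=True)
        st.spearman_clinical(measures, clinical).to_csv(
            out / "clinical_correlations.csv", index=False
        )


def stage_classify(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    cohort = _read_cohort(cfg)
    mask, atlas = _mask_atlas(cfg)
    Z = np.load(out / "zmaps.npy")
    Y = np.load(out / "harmonized.npy")
    analysis = np.load(out / "analysis_voxels.npy")
    Zm = np.where(analysis[None, :], Z, np.nan)
    labelled = cohort["response"].isin(["responder", "nonresponder"]).to_numpy()
    if labelled.sum() == 0 or cohort.loc[labelled, "response"].nunique() < 2:
        pd.DataFrame().to_csv(out / "roc_auc.csv", index=False)
        return

    striatum = atlas.region_mask(1, mask)
    summ = dev.summary_measures(
        Zm[labelled], cohort.loc[labelled, "subject_id"].tolist(),
        z_threshold=cfg.z_threshold,
    )
    scores = {
        "mean_z": summ["mean_z"].to_numpy(),
        "pct_pos": summ["pct_pos"].to_numpy(),
        "pct_neg": summ["pct_neg"].to_numpy(),
        "pct_tot": summ["pct_tot"].to_numpy(),
        "striatal_mean_z": np.nanmean(Zm[labelled][:, striatum], axis=1),
        "striatal_ki": Y[labelled][:, striatum].mean(axis=1),
    }
    labels = cohort.loc[labelled, "response"].to_numpy()
    rows = []
    for name in cfg.scores:
        r = roc_auc(scores[name], labels, score_name=name)
        _, lo, hi = auc_ci(scores[name], labels)
        rows.append(
            dict(score=name, auc=r.auc, ci_low=lo, ci_high=hi,
                 n_pos=r.n_pos, n_neg=r.n_neg, direction=r.direction)
        )
    pd.DataFrame(rows).to_csv(out / "roc_auc.csv", index=False)

    if {"striatal_mean_z", "striatal_ki"} <= set(cfg.scores):
        d = delong_compare(scores["striatal_mean_z"], scores["striatal_ki"], labels)
        (out / "delong.json").write_text(
            json.dumps(dict(auc_striatal_z=d.auc1, auc_striatal_ki=d.auc2,
                            delta=d.delta, z=d.z, p=d.p))
        )


STAGES = {
    "simulate": stage_simulate,
    "harmonize": stage_harmonize,
    "fit-nm": stage_fit_nm,
    "deviate": stage_deviate,
    "stats": stage_stats,
    "classify": stage_classify,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in order, writing a manifest at the end.

    A stage failure aborts with the stage name and leaves an INCOMPLETE
    marker next to the partial artifacts.
    """
    out = _out(cfg)
    names = stages or list(STAGES)
    timings = {}
    for name in names:
        t0 = time.perf_counter()
        try:
            STAGES[name](cfg)
        except Exception as exc:
            (out / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    (out / "INCOMPLETE").unlink(missing_ok=True)
    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in {"manifest.json"}
    )
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_timings_s": timings,
        "artifacts": {str(p.relative_to(out)): _checksum(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
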