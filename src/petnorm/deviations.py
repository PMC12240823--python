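"""Extreme-deviation analytics on Z-maps.

A voxel deviates extremely when Z > 2 (positive), Z < -2 (negative) or
|Z| > 2 (total); the thresholds are strict inequalities.  Under a calibrated
normative model the expected per-subject extreme fraction is the Gaussian
tail mass, so group-level excesses (summaries, overlap maps, risk ratios)
quantify pathology.  Non-converged voxels carry NaN and are excluded from
every numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging import AtlasParcellation, BrainMask

__all__ = [
    "summary_measures",
    "overlap_map",
    "RiskRatioResult",
    "risk_ratio",
    "regional_summary",
]

_SIGNS = ("pos", "neg", "tot")


def _extreme(Z: np.ndarray, sign: str, z_threshold: float = 2.0) -> np.ndarray:
    if sign == "pos":
        return Z > z_threshold
    if sign == "neg":
        return Z < -z_threshold
    if sign == "tot":
        return np.abs(Z) > z_threshold
    raise ValueError(f"sign must be one of {_SIGNS}, got {sign!r}")


def summary_measures(
    Z: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    voxel_sel: np.ndarray | None = None,
    z_threshold: float = 2.0,
    scope: str = "whole",
) -> pd.DataFrame:
    """Per-subject deviation summaries over the analyzed voxels.

    Returns one row per subject with ``mean_z`` and the percentages of
    analyzed voxels with Z > t (``pct_pos``), Z < -t (``pct_neg``) and
    |Z| > t (``pct_tot``); pct_tot = pct_pos + pct_neg holds exactly.
    ``voxel_sel`` restricts to a boolean selection of columns (e.g. a
    region); NaN (non-converged) voxels are excluded per subject.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    Z = np.asarray(Z, dtype=float)
    if voxel_sel is not None:
        Z = Z[:, np.asarray(voxel_sel, dtype=bool)]
    valid = np.isfinite(Z)
    n_valid = valid.sum(axis=1)
    if np.any(n_valid == 0):
        raise ValueError("a subject has no analyzable voxels in this scope")
    with np.errstate(invalid="ignore"):
        mean_z = np.nansum(np.where(valid, Z, 0.0), axis=1) / n_valid
        pos = np.sum(np.where(valid, Z > z_threshold, False), axis=1)
        neg = np.sum(np.where(valid, Z < -z_threshold, False), axis=1)
    ids = (
        list(subject_ids)
        if subject_ids is not None
        else [str(i) for i in range(Z.shape[0])]
    )
    return pd.DataFrame(
        {
            "subject_id": ids,
            "scope": scope,
            "mean_z": mean_z,
            "pct_pos": 100.0 * pos / n_valid,
            "pct_neg": 100.0 * neg / n_valid,
            "pct_tot": 100.0 * (pos + neg) / n_valid,
            "n_voxels": n_valid,
        }
    )


def overlap_map(
    Z: np.ndarray,
    sign: str = "tot",
    z_threshold: float = 2.0,
) -> np.ndarray:
    """Per-voxel percentage of subjects with an extreme deviation.

    Chance level is ~2.5% for ``pos``/``neg`` and ~5% for ``tot``; display
    thresholding at chance is a rendering choice, not applied here.  Voxels
    that are NaN for a subject do not count toward that voxel's denominator.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] == 0:
        raise ValueError("subject subset is empty")
    valid = np.isfinite(Z)
    ext = _extreme(np.where(valid, Z, 0.0), sign, z_threshold) & valid
    denom = valid.sum(axis=0).astype(float)
    out = np.full(Z.shape[1], np.nan)
    ok = denom > 0
    out[ok] = 100.0 * ext.sum(axis=0)[ok] / denom[ok]
    return out


@dataclass(frozen=True)
class RiskRatioResult:
    """Pooled 2×2 voxel-count risk ratio, patients vs controls."""

    a: float  # extreme voxel-subject pairs, patients
    b: float  # non-extreme, patients
    c: float  # extreme, controls
    d: float  # non-extreme, controls
    rr: float
    ci_low: float
    ci_high: float
    sign: str
    continuity_corrected: bool = False

    @property
    def significant(self) -> bool:
        """CI excludes 1 (the no-excess null)."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def risk_ratio(
    Z_patients: np.ndarray,
    Z_controls: np.ndarray,
    sign: str = "tot",
    z_threshold: float = 2.0,
    per_subject: bool = False,
) -> RiskRatioResult:
    """Risk ratio of extreme-deviation voxel proportions, patients vs HC.

    Default counting pools voxel-subject pairs into a single 2×2 table per
    group: RR = [a/(a+b)] / [c/(c+d)] with a 95% Wald CI on the log scale,
    exp(ln RR ± 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).  If an extreme
    cell is empty, 0.5 is added to every cell (continuity correction) and
    the result is flagged.  ``per_subject=True`` instead averages
    per-subject extreme fractions before forming the ratio (alternative
    counting; same CI construction on the pooled-equivalent counts).
    """
    Zp = np.asarray(Z_patients, dtype=float)
    Zc = np.asarray(Z_controls, dtype=float)
    if Zp.shape[0] == 0 or Zc.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if Zp.shape[1] != Zc.shape[1]:
        raise ValueError("groups must share the same voxel set")

    def _counts(Z):
        valid = np.isfinite(Z)
        ext = _extreme(np.where(valid, Z, 0.0), sign, z_threshold) & valid
        if per_subject:
            frac = ext.sum(axis=1) / valid.sum(axis=1)
            total = float(valid.sum())
            extreme = float(frac.mean() * total)
        else:
            total = float(valid.sum())
            extreme = float(ext.sum())
        return extreme, total - extreme

    a, b = _counts(Zp)
    c, d = _counts(Zc)
    corrected = a == 0 or c == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    lo, hi = np.exp(np.log(rr) - 1.96 * se), np.exp(np.log(rr) + 1.96 * se)
    return RiskRatioResult(a, b, c, d, float(rr), float(lo), float(hi), sign, corrected)


def regional_summary(
    Z: np.ndarray,
    atlas: AtlasParcellation,
    mask: BrainMask,
    region: int | str | None = None,
    subject_ids: Sequence[str] | None = None,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Summary measures restricted to atlas regions.

    ``region`` may be a label, a region name, or None for all regions;
    a region with no analyzable voxels inside the mask is an error.
    """
    name_to_label = {v: k for k, v in atlas.names.items()}
    if region is None:
        labels = sorted(atlas.names)
    elif isinstance(region, str):
        if region not in name_to_label:
            raise KeyError(f"unknown region name {region!r}")
        labels = [name_to_label[region]]
    else:
        if region not in atlas.names:
            raise KeyError(f"unknown region label {region}")
        labels = [int(region)]
    frames = []
    for lab in labels:
        sel = atlas.region_mask(lab, mask)
        if not sel.any():
            raise ValueError(
                f"region {atlas.names[lab]!r} does not intersect the analysis mask"
            )
        frames.append(
            summary_measures(
                Z, subject_ids, voxel_sel=sel, z_threshold=z_threshold,
                scope=atlas.names[lab],
            )
        )
    return pd.concat(frames, ignore_index=True)
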