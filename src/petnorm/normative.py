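"""Voxel-wise Bayesian linear regression normative models.

One independent Bayesian linear regression per masked voxel relates the
parametric PET value to demographic covariates in a reference cohort:

    y = X w + eps,   eps ~ N(0, 1/beta),   w ~ N(0, (1/alpha) I)

The hyperparameters (alpha, beta) are set by maximizing the log marginal
likelihood (type-II maximum likelihood / evidence) with a derivative-free
Powell search over (log alpha, log beta).  A scored subject's deviation is
the Z-score of the observation under the posterior predictive:

    Z = (y* - x*' m) / sqrt(1/beta + x*' A^-1 x*)

with m, A the weight posterior mean and precision — the denominator includes
parameter uncertainty, which keeps Z honest at small reference n.

Voxels where the evidence optimization fails, or whose values are constant,
are flagged non-converged and carry NaN sentinels; every downstream analysis
excludes them.  Model quality is summarized per voxel by the cross-validated
explained variance EXPV = 1 - Var(y - yhat)/Var(y), which is negative when
the model is worse than predicting the mean — the standard non-convergence
criterion used to build analysis masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .imaging import BrainMask

__all__ = [
    "DesignSpec",
    "build_design",
    "fit_blr_voxel",
    "explained_variance",
    "NormativeBLR",
    "DeviationMaps",
    "crossval_deviations",
    "expv_mask",
]

_ALLOWED_COVARIATES = ("age", "sex", "bmi")
_STANDARDIZED = ("age", "bmi")  # sex stays as its {0, 1} coding


@dataclass
class DesignSpec:
    """Covariate list plus the reference-cohort standardization constants.

    The design matrix always starts with an intercept column; age and BMI
    are standardized by the *reference* cohort's mean/SD (stored here), so
    patient designs are built on the reference scale.
    """

    covariates: tuple[str, ...] = ("age", "sex")
    center: dict | None = None  # covariate → (mean, sd) learned on reference

    def __post_init__(self) -> None:
        bad = [c for c in self.covariates if c not in _ALLOWED_COVARIATES]
        if bad:
            raise ValueError(f"unsupported covariates {bad}; allowed: {_ALLOWED_COVARIATES}")
        self.covariates = tuple(self.covariates)

    @property
    def n_columns(self) -> int:
        return 1 + len(self.covariates)


def build_design(
    cohort: pd.DataFrame,
    spec: DesignSpec,
    fit_reference: bool = False,
) -> np.ndarray:
    """Build the [1 | covariates] design matrix for a cohort table.

    With ``fit_reference=True`` the standardization constants are learned
    from this cohort and stored on the spec; otherwise the stored reference
    constants are applied (patient designs use reference statistics).
    """
    cols = [np.ones(len(cohort))]
    missing_cols = [c for c in spec.covariates if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks covariate columns {missing_cols}")
    for c in spec.covariates:
        x = pd.to_numeric(cohort[c], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            bad = cohort.loc[~np.isfinite(x), "subject_id"].tolist() \
                if "subject_id" in cohort.columns else list(np.flatnonzero(~np.isfinite(x)))
            raise ValueError(f"missing values in covariate {c!r} for subjects {bad}")
        if c in _STANDARDIZED:
            if fit_reference:
                mu, sd = float(x.mean()), float(x.std())
                if sd == 0:
                    raise ValueError(f"covariate {c!r} is constant in the reference")
                spec.center = dict(spec.center or {})
                spec.center[c] = (mu, sd)
            if spec.center is None or c not in spec.center:
                raise ValueError(
                    f"no reference standardization for {c!r}; build the "
                    "reference design first"
                )
            mu, sd = spec.center[c]
            x = (x - mu) / sd
        cols.append(x)
    return np.column_stack(cols)


def _evidence_terms(X: np.ndarray):
    """Shared eigen-decomposition of X'X for fast per-voxel evidence."""
    XtX = X.T @ X
    lam, Q = np.linalg.eigh(XtX)
    lam = np.maximum(lam, 0.0)
    return lam, Q


def _neg_log_evidence(
    params: np.ndarray, lam: np.ndarray, c: np.ndarray, yty: float, n: int
) -> float:
    """-log p(y | alpha, beta) in the eigenbasis of X'X.

    ``c`` is Q' X'y; the weight posterior mean in that basis is
    beta * c / (alpha + beta * lam).
    """
    log_a, log_b = params
    if abs(log_a) > 40 or abs(log_b) > 40:
        return 1e12
    alpha, beta = np.exp(log_a), np.exp(log_b)
    denom = alpha + beta * lam
    m_t = beta * c / denom
    mtm = float(m_t @ m_t)
    rss = yty - 2.0 * float(m_t @ c) + float((lam * m_t) @ m_t)
    rss = max(rss, 0.0)
    p = len(lam)
    log_ev = (
        0.5 * p * log_a
        + 0.5 * n * log_b
        - 0.5 * (beta * rss + alpha * mtm)
        - 0.5 * float(np.sum(np.log(denom)))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return -log_ev if np.isfinite(log_ev) else 1e12


def fit_blr_voxel(
    y: np.ndarray, X: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray, bool]:
    """Fit one voxel's BLR by Powell evidence maximization.

    Returns (alpha, beta, m, A, converged); constant-valued voxels are
    flagged non-converged rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > {p + 2} subjects to fit {p} design columns")
    var_y = float(y.var())
    if var_y <= 0:
        return np.nan, np.nan, np.full(p, np.nan), np.full((p, p), np.nan), False
    lam, Q = _evidence_terms(X)
    c = Q.T @ (X.T @ y)
    yty = float(y @ y)
    x0 = np.array([0.0, np.log(1.0 / var_y)])
    res = optimize.minimize(
        _neg_log_evidence,
        x0,
        args=(lam, c, yty, n),
        method="Powell",
        options=dict(xtol=1e-4, ftol=1e-6, maxiter=200),
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    alpha, beta = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    denom = alpha + beta * lam
    m = Q @ (beta * c / denom)
    A = Q @ np.diag(denom) @ Q.T
    return alpha, beta, m, A, converged


def explained_variance(y: np.ndarray, yhat: np.ndarray) -> float:
    """EXPV = 1 - Var(y - yhat)/Var(y), population variances; may be < 0.

    Returns NaN when Var(y) = 0 (undefined).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    var_y = float(y.var())
    if var_y == 0.0:
        return np.nan
    return 1.0 - float((y - yhat).var()) / var_y


class NormativeBLR(BaseEstimator):
    """Set of per-voxel Bayesian linear regression normative models.

    ``fit`` takes the reference cohort table and a subjects × voxels value
    matrix; ``predict`` returns posterior-predictive means and
    ``predict_z`` the deviation Z-scores of new observations.

    Fitted attributes
    -----------------
    design_ : DesignSpec with reference standardization constants
    alpha_, beta_ : per-voxel prior and noise precision
    coef_ : n_voxels × n_columns weight posterior means
    denom_ : n_voxels × n_columns posterior precision eigenvalues
             (alpha + beta lambda_j in the shared eigenbasis ``Q_``)
    converged_ : per-voxel convergence flags
    expv_ : per-voxel explained variance (set by cross-validation)
    """

    def __init__(self, covariates: Sequence[str] = ("age", "sex")):
        self.covariates = tuple(covariates)

    def fit(self, cohort: pd.DataFrame, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != len(cohort):
            raise ValueError("Y must be subjects × voxels matching the cohort")
        self.design_ = DesignSpec(self.covariates)
        X = build_design(cohort, self.design_, fit_reference=True)
        n, p = X.shape
        nv = Y.shape[1]
        lam, Q = _evidence_terms(X)
        self.Q_ = Q
        self.lam_ = lam
        self.n_train_ = n

        alpha = np.full(nv, np.nan)
        beta = np.full(nv, np.nan)
        coef = np.full((nv, p), np.nan)
        denom = np.full((nv, p), np.nan)
        converged = np.zeros(nv, dtype=bool)
        Xty = X.T @ Y  # p × nv
        yty = np.einsum("ij,ij->j", Y, Y)
        var_y = Y.var(axis=0)
        x0_base = np.array([0.0, 0.0])
        for v in range(nv):
            if var_y[v] <= 0:
                continue
            c = Q.T @ Xty[:, v]
            x0 = x0_base.copy()
            x0[1] = np.log(1.0 / var_y[v])
            res = optimize.minimize(
                _neg_log_evidence,
                x0,
                args=(lam, c, float(yty[v]), n),
                method="Powell",
                options=dict(xtol=1e-4, ftol=1e-6, maxiter=200),
            )
            if not (res.success and np.isfinite(res.fun)):
                continue
            a_v, b_v = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            d = a_v + b_v * lam
            alpha[v], beta[v] = a_v, b_v
            denom[v] = d
            coef[v] = Q @ (b_v * c / d)
            converged[v] = True
        self.alpha_ = alpha
        self.beta_ = beta
        self.coef_ = coef
        self.denom_ = denom
        self.converged_ = converged
        self.expv_ = np.full(nv, np.nan)
        self.n_features_in_ = nv
        return self

    # -- scoring ------------------------------------------------------------
    def _design(self, cohort: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "design_"):
            raise RuntimeError("NormativeBLR is not fitted")
        return build_design(cohort, self.design_)

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        """Posterior-predictive mean per subject × voxel (NaN where unfit)."""
        X = self._design(cohort)
        return X @ self.coef_.T

    def predictive_sd(self, cohort: pd.DataFrame) -> np.ndarray:
        """Posterior-predictive SD: sqrt(1/beta + x*' A^-1 x*)."""
        X = self._design(cohort)
        Xt = X @ self.Q_  # rotate into the shared eigenbasis
        with np.errstate(divide="ignore", invalid="ignore"):
            param_var = (Xt**2) @ (1.0 / self.denom_).T  # n* × nv
            return np.sqrt(1.0 / self.beta_[None, :] + param_var)

    def predict_z(self, cohort: pd.DataFrame, Y: np.ndarray) -> np.ndarray:
        """Deviation Z-scores of observed values under the normative model.

        Non-converged voxels yield NaN for every subject.
        """
        Y = np.asarray(Y, dtype=float)
        z = (Y - self.predict(cohort)) / self.predictive_sd(cohort)
        z[:, ~self.converged_] = np.nan
        return z

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        if not hasattr(self, "coef_"):
            raise RuntimeError("NormativeBLR is not fitted")
        payload = {
            "format": "petnorm-blr/1",
            "covariates": list(self.covariates),
            "center": self.design_.center,
            "n_train": self.n_train_,
            "Q": self.Q_.tolist(),
            "lam": self.lam_.tolist(),
            "alpha": self.alpha_.tolist(),
            "beta": self.beta_.tolist(),
            "coef": self.coef_.tolist(),
            "denom": self.denom_.tolist(),
            "converged": self.converged_.astype(int).tolist(),
            "expv": self.expv_.tolist(),
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeBLR":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "petnorm-blr/1":
            raise ValueError(f"{path}: not a serialized normative model set")
        model = cls(covariates=payload["covariates"])
        model.design_ = DesignSpec(tuple(payload["covariates"]))
        model.design_.center = (
            {k: tuple(v) for k, v in payload["center"].items()}
            if payload["center"]
            else None
        )
        model.n_train_ = int(payload["n_train"])
        model.Q_ = np.asarray(payload["Q"], dtype=float)
        model.lam_ = np.asarray(payload["lam"], dtype=float)
        model.alpha_ = np.asarray(payload["alpha"], dtype=float)
        model.beta_ = np.asarray(payload["beta"], dtype=float)
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.denom_ = np.asarray(payload["denom"], dtype=float)
        model.converged_ = np.asarray(payload["converged"], dtype=bool)
        model.expv_ = np.asarray(payload["expv"], dtype=float)
        model.n_features_in_ = len(model.alpha_)
        return model


@dataclass
class DeviationMaps:
    """Per-subject per-voxel Z-scores with their provenance."""

    subject_ids: list[str]
    Z: np.ndarray  # n_subjects × n_masked_voxels, NaN at non-converged voxels
    provenance: str  # "cross-validated" | "out-of-sample"
    model: NormativeBLR | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[0] != len(self.subject_ids):
            raise ValueError("Z rows must match subject_ids")


def crossval_deviations(
    Y: np.ndarray,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    k: int = 5,
    seed: int = 0,
) -> tuple[DeviationMaps, np.ndarray]:
    """k-fold cross-validated deviation maps and explained variance.

    Subjects are partitioned by a seeded shuffle; each fold is scored by a
    model fit on the remaining folds.  EXPV per voxel is computed on the
    concatenated out-of-fold predictive means.  Default k = 5.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if n < 2 * k:
        raise ValueError(f"need at least 2k = {2 * k} subjects, got {n}")
    p = 1 + len(covariates)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    if min(len(f) for f in folds) < 1 or (n - max(len(f) for f in folds)) < p + 3:
        raise ValueError("a training split would be too small for the design")

    Z = np.full_like(Y, np.nan)
    yhat = np.full_like(Y, np.nan)
    conv_all = np.ones(Y.shape[1], dtype=bool)
    cohort = cohort.reset_index(drop=True)
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        model = NormativeBLR(covariates=covariates).fit(
            cohort.iloc[train_idx], Y[train_idx]
        )
        Z[test_idx] = model.predict_z(cohort.iloc[test_idx], Y[test_idx])
        yhat[test_idx] = model.predict(cohort.iloc[test_idx])
        conv_all &= model.converged_

    expv = np.full(Y.shape[1], np.nan)
    var_y = Y.var(axis=0)
    ok = conv_all & (var_y > 0)
    expv[ok] = 1.0 - (Y[:, ok] - yhat[:, ok]).var(axis=0) / var_y[ok]

    ids = (
        cohort["subject_id"].tolist()
        if "subject_id" in cohort.columns
        else [str(i) for i in range(n)]
    )
    return DeviationMaps(ids, Z, "cross-validated"), expv


def expv_mask(
    model: NormativeBLR,
    threshold: float,
    mask: BrainMask,
) -> BrainMask:
    """Analysis mask from converged voxels exceeding an EXPV threshold.

    Thresholds below 0.10 are applied strictly (EXPV > t); the conservative
    0.10 level (the L-curve optimum convention) is applied inclusively
    (EXPV ≥ t).
    """
    expv = model.expv_
    if np.all(np.isnan(expv)):
        raise ValueError("model has no EXPV values; run cross-validation first")
    with np.errstate(invalid="ignore"):
        keep = expv >= threshold if threshold >= 0.10 else expv > threshold
    keep = keep & model.converged_ & np.isfinite(expv)
    if not keep.any():
        raise ValueError(f"EXPV threshold {threshold:g} leaves no voxels")
    return BrainMask(mask.grid, mask.insert(keep.astype(float)) > 0.5)
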