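"""Treatment-response classification: ROC/AUC and the DeLong test.

The AUC is computed by pair counting (ties count 1/2), which makes it
identical to the normalized Mann–Whitney U statistic and invariant under
strictly monotone transforms of the scores.  Correlated ROC curves computed
on the same subjects are compared with DeLong's structural-components test.
Score orientation is never flipped silently: the reported AUC refers to the
stated positive class, with the direction recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ROCResult", "roc_auc", "auc_ci", "DeLongResult", "delong_compare"]


def _binary_labels(labels: Sequence, positive: str) -> np.ndarray:
    lab = np.asarray(labels).astype(str)
    classes = set(lab)
    if positive not in classes or len(classes - {positive}) == 0:
        raise ValueError(
            f"need both classes present; got {sorted(classes)} with "
            f"positive={positive!r}"
        )
    return lab == positive


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 if x < y
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with its pair-counting AUC."""

    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    score_name: str = ""
    positive_class: str = "responder"

    @property
    def direction(self) -> str:
        """Whether larger scores favour the positive class."""
        return "higher-score→positive" if self.auc >= 0.5 else "higher-score→negative"


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    positive: str = "responder",
    score_name: str = "",
) -> ROCResult:
    """Empirical ROC curve and AUC of a score for a binary label.

    AUC is the probability that a random positive outscores a random
    negative (ties count 1/2).  The direction of the score is reported, not
    auto-corrected: an AUC below 0.5 means larger scores favour the
    negative class.
    """
    scores = np.asarray(scores, dtype=float)
    is_pos = _binary_labels(labels, positive)
    pos, neg = scores[is_pos], scores[~is_pos]
    v10, _ = _placements(pos, neg)
    auc = float(v10.mean())

    # ROC polyline: sweep thresholds from +inf down through unique scores
    order = np.argsort(-scores, kind="stable")
    sorted_pos = is_pos[order]
    uniq_mask = np.append(np.diff(scores[order]) != 0, True)
    tp = np.cumsum(sorted_pos)[uniq_mask]
    fp = np.cumsum(~sorted_pos)[uniq_mask]
    thresholds = np.concatenate([[np.inf], scores[order][uniq_mask]])
    tpr = np.concatenate([[0.0], tp / len(pos)])
    fpr = np.concatenate([[0.0], fp / len(neg)])
    return ROCResult(
        thresholds, fpr, tpr, auc, len(pos), len(neg), score_name, positive
    )


def auc_ci(
    scores: Sequence[float],
    labels: Sequence,
    positive: str = "responder",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """AUC with its DeLong-variance Wald confidence interval.

    Returns (auc, ci_low, ci_high), clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    is_pos = _binary_labels(labels, positive)
    m, n = int(is_pos.sum()), int((~is_pos).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class for a variance")
    v10, v01 = _placements(scores[is_pos], scores[~is_pos])
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    half = sps.norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    return auc, max(auc - half, 0.0), min(auc + half, 1.0)


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two correlated AUCs."""

    auc1: float
    auc2: float
    delta: float
    z: float
    p: float
    var_delta: float
    cov: np.ndarray  # 2×2 covariance of (auc1, auc2)


def delong_compare(
    scores1: Sequence[float],
    scores2: Sequence[float],
    labels: Sequence,
    positive: str = "responder",
) -> DeLongResult:
    """DeLong test for two ROC curves measured on the same subjects.

    Uses the structural components per positive (V10) and per negative
    (V01); the covariance of the two AUCs is the sum of the component
    sample covariances scaled by the class sizes.  Identical scores give
    delta = 0, p = 1.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("both scores must cover the same subjects")
    is_pos = _binary_labels(labels, positive)
    m, n = int(is_pos.sum()), int((~is_pos).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 subjects per class for a variance")

    V10 = np.empty((2, m))
    V01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((s1, s2)):
        v10, v01 = _placements(s[is_pos], s[~is_pos])
        V10[k], V01[k] = v10, v01
        aucs[k] = v10.mean()
    S10 = np.cov(V10)  # 2×2
    S01 = np.cov(V01)
    cov = S10 / m + S01 / n
    delta = float(aucs[0] - aucs[1])
    var_delta = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var_delta <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(
        float(aucs[0]), float(aucs[1]), delta, float(z), p, var_delta, cov
    )
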