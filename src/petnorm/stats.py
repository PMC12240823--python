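"""Rank-based and permutation inference for deviation maps.

Implements the statistical machinery the deviation analysis relies on:

* Scheirer–Ray–Hare two-way ANOVA on ranks (factorial nonparametric test),
* tie-corrected Kruskal–Wallis with eta-squared effect size,
* Mann–Whitney U with the rank-biserial-style effect size r = |Z|/sqrt(N),
* voxel-wise permutation GLM with Freedman–Lane residual permutation,
  max-statistic family-wise error correction and optional threshold-free
  cluster enhancement (TFCE),
* connected-component cluster extraction,
* Spearman correlations between per-subject summary measures and clinical
  scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .imaging import BrainMask

__all__ = [
    "RankTestResult",
    "StatMapResult",
    "ClusterSet",
    "scheirer_ray_hare",
    "kruskal_eta2",
    "mann_whitney_effect",
    "permutation_glm",
    "tfce_enhance",
    "extract_clusters",
    "spearman_clinical",
]


@dataclass(frozen=True)
class RankTestResult:
    """One rank test: statistic, df, p, and an effect size with CI."""

    name: str
    statistic: float
    df: float | None
    p: float
    effect_name: str | None = None
    effect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def as_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect": self.effect_name,
            "effect_size": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _dummies(codes: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded indicator columns (first level dropped)."""
    levels = np.unique(codes)
    return np.column_stack([(codes == lv).astype(float) for lv in levels[1:]])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def scheirer_ray_hare(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, RankTestResult]:
    """Scheirer–Ray–Hare two-way ANOVA on ranks.

    Ranks all values with average ties, decomposes the rank sums of squares
    sequentially (A, then B, then A×B), and refers each
    H = SS_effect / MS_total (MS_total = total rank SS / (N-1), which embeds
    the tie correction) to a chi-squared distribution with the effect's df.

    Returns results keyed ``"A"``, ``"B"``, ``"AxB"``.
    """
    values = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if values.ndim != 1 or len(a) != len(values) or len(b) != len(values):
        raise ValueError("values and both factors must be equal-length 1-D")
    lv_a, lv_b = np.unique(a), np.unique(b)
    if len(lv_a) < 2 and len(lv_b) < 2:
        raise ValueError("at least one factor needs ≥ 2 levels")
    for la in lv_a:
        for lb in lv_b:
            if not np.any((a == la) & (b == lb)):
                raise ValueError(f"empty cell ({la!r}, {lb!r})")

    r = sps.rankdata(values)
    n = len(r)
    ss_total = float(np.sum((r - r.mean()) ** 2))
    if ss_total == 0.0:  # all values identical: every effect is null
        out = {}
        for key, lv in (("A", lv_a), ("B", lv_b)):
            out[key] = RankTestResult(f"SRH {key}", 0.0, max(len(lv) - 1, 0), 1.0)
        out["AxB"] = RankTestResult(
            "SRH AxB", 0.0, max((len(lv_a) - 1) * (len(lv_b) - 1), 0), 1.0
        )
        return out
    ms_total = ss_total / (n - 1)

    ones = np.ones((n, 1))
    Xa = _dummies(a) if len(lv_a) > 1 else np.empty((n, 0))
    Xb = _dummies(b) if len(lv_b) > 1 else np.empty((n, 0))
    if Xa.shape[1] and Xb.shape[1]:
        Xab = np.column_stack(
            [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        )
    else:
        Xab = np.empty((n, 0))

    rss0 = _rss(r, ones)
    rss_a = _rss(r, np.hstack([ones, Xa]))
    rss_ab = _rss(r, np.hstack([ones, Xa, Xb]))
    rss_full = _rss(r, np.hstack([ones, Xa, Xb, Xab]))

    def _result(key: str, ss: float, df: int) -> RankTestResult:
        h = ss / ms_total
        p = float(sps.chi2.sf(h, df)) if df > 0 else 1.0
        return RankTestResult(f"SRH {key}", float(h), df, p)

    return {
        "A": _result("A", rss0 - rss_a, len(lv_a) - 1),
        "B": _result("B", rss_a - rss_ab, len(lv_b) - 1),
        "AxB": _result("AxB", rss_ab - rss_full, (len(lv_a) - 1) * (len(lv_b) - 1)),
    }


def _eta2_from_h(h: float, k: int, n: int) -> float:
    # eta^2 = (H - k + 1)/(N - k); may be negative near the null
    return (h - k + 1) / (n - k)


def kruskal_eta2(
    values: Sequence[float],
    groups: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H with eta-squared effect size.

    The eta-squared CI comes from a within-group bootstrap (``n_boot``
    draws); eta-squared is allowed to be negative near the null.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    k, n = len(levels), len(values)
    if k < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    try:
        h, p = sps.kruskal(*samples)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    eta2 = _eta2_from_h(float(h), k, n)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        resampled = [s[rng.integers(0, len(s), len(s))] for s in samples]
        try:
            hb, _ = sps.kruskal(*resampled)
        except ValueError:
            hb = 0.0
        boots[i] = _eta2_from_h(float(hb), k, n)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RankTestResult(
        "Kruskal-Wallis", float(h), k - 1, float(p), "eta2", eta2, float(lo), float(hi)
    )


def _u_and_z(
    x: np.ndarray, y: np.ndarray, continuity: bool = True
) -> tuple[float, float]:
    """Mann–Whitney U of x and its tie-corrected normal-approximation Z.

    ``continuity`` applies the usual 0.5 correction toward the null mean.
    """
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    n = nx + ny
    mean_u = nx * ny / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    num = u_x - mean_u
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = 0.0 if var_u == 0 else num / np.sqrt(var_u)
    return u_x, z


def mann_whitney_effect(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    continuity: bool = True,
) -> RankTestResult:
    """Mann–Whitney U (normal approximation, tie-corrected) with r = |Z|/sqrt(N).

    The effect-size CI is a within-group bootstrap percentile interval.
    Disable ``continuity`` to recover the exact algebraic equivalence with
    the two-group Kruskal–Wallis chi-squared (H = Z^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    u, z = _u_and_z(x, y, continuity=continuity)
    n = len(x) + len(y)
    p = float(2 * sps.norm.sf(abs(z)))
    r = abs(z) / np.sqrt(n)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        xb = x[rng.integers(0, len(x), len(x))]
        yb = y[rng.integers(0, len(y), len(y))]
        _, zb = _u_and_z(xb, yb)
        boots[i] = abs(zb) / np.sqrt(n)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RankTestResult(
        "Mann-Whitney", u, None, p, "rank r", float(r), float(lo), float(hi)
    )


# --------------------------------------------------------------------------
# permutation GLM with TFCE and max-statistic FWE
# --------------------------------------------------------------------------

_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def tfce_enhance(
    stat: np.ndarray,
    E: float = 0.5,
    H_exp: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative 3-D stat field.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... ≤ stat(v) of
    extent(v, h)^E · h^H_exp · dh, where extent is the size of the connected
    component containing v at threshold h.  ``dh`` defaults to max(stat)/100.
    """
    stat = np.asarray(stat, dtype=float)
    if stat.ndim != 3:
        raise ValueError("tfce_enhance expects a 3-D field")
    if stat.min() < 0:
        raise ValueError("stat field must be non-negative (enhance |stat| per sign)")
    peak = stat.max()
    if peak <= 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = peak / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = _CONNECTIVITY[connectivity]
    out = np.zeros_like(stat)
    h = dh
    while h <= peak + 1e-12:
        above = stat >= h
        labels, n_lab = ndimage.label(above, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = np.zeros(n_lab + 1)
        contrib[1:] = sizes[1:].astype(float) ** E * h**H_exp * dh
        out += contrib[labels]
        h += dh
    return out


@dataclass
class StatMapResult:
    """Voxel-wise permutation GLM output over the masked voxels."""

    stat: np.ndarray            # observed F (or t) per masked voxel
    p_uncorrected: np.ndarray   # permutation p per voxel
    p_fwe: np.ndarray           # max-statistic FWE-corrected p per voxel
    n_permutations: int
    enhancement: str            # "none" | "tfce"
    tfce_params: dict = field(default_factory=dict)
    seed: int = 0
    df: tuple[float, float] | None = None
    mask: BrainMask | None = None


def permutation_glm(
    Y: np.ndarray,
    groups: Sequence,
    nuisance: np.ndarray | None = None,
    interaction_with: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    enhancement: str = "none",
    mask: BrainMask | None = None,
    tfce_E: float = 0.5,
    tfce_H: float = 2.0,
    tfce_dh: float | None = None,
    connectivity: int = 26,
) -> StatMapResult:
    """Voxel-wise permutation F-test with Freedman–Lane residual permutation.

    Tests the ``groups`` factor (or, when ``interaction_with`` is given, the
    groups × second-factor interaction, permuting residuals under the
    main-effects model).  The family-wise error correction uses the
    permutation distribution of the image-wise maximum of the — optionally
    TFCE-enhanced — statistic:
    p_FWE(v) = (1 + #{perm max ≥ observed(v)}) / (1 + n_perm).

    ``Y`` is subjects × masked voxels; TFCE requires ``mask`` to place the
    statistic back on its 3-D grid.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    n = Y.shape[0]
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    if enhancement not in ("none", "tfce"):
        raise ValueError(f"unknown enhancement {enhancement!r}")
    if enhancement == "tfce" and mask is None:
        raise ValueError("TFCE needs the BrainMask to rebuild 3-D fields")

    ones = np.ones((n, 1))
    Xg = _dummies(groups)
    if Xg.shape[1] == 0:
        raise ValueError("groups factor needs ≥ 2 levels")
    nuis_cols = [ones]
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        nuis_cols.append(nuis if nuis.ndim == 2 else nuis[:, None])
    if interaction_with is not None:
        # interaction test: main effects of both factors become nuisance
        Xb = _dummies(np.asarray(interaction_with))
        effect = np.column_stack(
            [Xg[:, i] * Xb[:, j] for i in range(Xg.shape[1]) for j in range(Xb.shape[1])]
        )
        nuis_cols.extend([Xg, Xb])
    else:
        effect = Xg
    X_reduced = np.hstack(nuis_cols)
    X_full = np.hstack([X_reduced, effect])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank deficient")

    # precomputed residual-maker matrices: per-permutation cost is two
    # (n × n)(n × v) products instead of repeated least-squares solves
    def _residual_maker(X: np.ndarray) -> np.ndarray:
        return np.eye(n) - X @ np.linalg.pinv(X)

    R_full = _residual_maker(X_full)
    R_red = _residual_maker(X_reduced)
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = n - X_full.shape[1]
    if df2 < 1:
        raise ValueError("design leaves no error degrees of freedom")

    def _fast_f(yy: np.ndarray) -> np.ndarray:
        rss_f = np.einsum("ij,ij->j", R_full @ yy, R_full @ yy)
        rss_r = np.einsum("ij,ij->j", R_red @ yy, R_red @ yy)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_r - rss_f) / df1) / (rss_f / df2)
        return np.nan_to_num(np.maximum(f, 0.0))

    def _stat_image(yy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = _fast_f(yy)
        if enhancement == "tfce":
            # enhance sqrt(F): the default E/H exponents are calibrated for
            # t-scale statistics, and F grows as t^2
            vol = mask.insert(np.sqrt(f))
            enh = tfce_enhance(
                vol, E=tfce_E, H_exp=tfce_H, dh=tfce_dh, connectivity=connectivity
            )
            return f, mask.extract(enh)
        return f, f

    obs_f, obs_enh = _stat_image(Y)

    # Freedman–Lane: permute reduced-model residuals, keep the nuisance fit
    resid_r = R_red @ Y
    fitted_r = Y - resid_r

    rng = np.random.default_rng(seed)
    exceed_unc = np.zeros(Y.shape[1])
    exceed_fwe = np.zeros(Y.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, enh_p = _stat_image(fitted_r + resid_r[perm])
        exceed_unc += enh_p >= obs_enh
        exceed_fwe += enh_p.max() >= obs_enh
    p_unc = (1.0 + exceed_unc) / (1.0 + n_perm)
    p_fwe = (1.0 + exceed_fwe) / (1.0 + n_perm)

    return StatMapResult(
        stat=obs_f,
        p_uncorrected=p_unc,
        p_fwe=p_fwe,
        n_permutations=n_perm,
        enhancement=enhancement,
        tfce_params=(
            dict(E=tfce_E, H_exp=tfce_H, dh=tfce_dh, connectivity=connectivity)
            if enhancement == "tfce"
            else {}
        ),
        seed=seed,
        df=(float(df1), float(df2)),
        mask=mask,
    )


@dataclass
class ClusterSet:
    """Disjoint significant clusters with per-subject mean deviations."""

    clusters: list[dict]  # voxel_idx, size, peak_stat, peak_ijk, mean_z

    def __len__(self) -> int:
        return len(self.clusters)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i + 1,
                "size": c["size"],
                "peak_stat": c["peak_stat"],
                "peak_i": c["peak_ijk"][0],
                "peak_j": c["peak_ijk"][1],
                "peak_k": c["peak_ijk"][2],
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(rows)


def extract_clusters(
    result: StatMapResult,
    mask: BrainMask | None = None,
    alpha: float = 0.05,
    min_size: int = 50,
    Z: np.ndarray | None = None,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of {p_FWE < alpha}, discarding those < min_size.

    When a deviation matrix ``Z`` (subjects × masked voxels) is provided, the
    per-subject mean deviation within each cluster is returned for post-hoc
    tests.  An empty ClusterSet is a valid outcome.
    """
    mask = mask if mask is not None else result.mask
    if mask is None:
        raise ValueError("need the BrainMask to form spatial clusters")
    sig = result.p_fwe < alpha
    vol = mask.insert(sig.astype(float)) > 0.5
    labels, n_lab = ndimage.label(vol, structure=_CONNECTIVITY[connectivity])
    lab_vec = mask.extract(labels.astype(float)).astype(int)
    clusters = []
    for lab in range(1, n_lab + 1):
        sel = lab_vec == lab
        size = int(sel.sum())
        if size < min_size:
            continue
        stats_in = result.stat[sel]
        peak_pos = np.flatnonzero(sel)[int(np.argmax(stats_in))]
        full_idx = mask.flat_indices[peak_pos]
        peak_ijk = tuple(
            int(v) for v in np.unravel_index(full_idx, mask.grid.dims, order="F")
        )
        clusters.append(
            dict(
                voxel_idx=np.flatnonzero(sel),
                size=size,
                peak_stat=float(stats_in.max()),
                peak_ijk=peak_ijk,
                mean_z=(Z[:, sel].mean(axis=1) if Z is not None else None),
            )
        )
    clusters.sort(key=lambda c: -c["size"])
    return ClusterSet(clusters)


def spearman_clinical(
    measures: pd.DataFrame,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho and two-sided p for every (measure, clinical) pair.

    Missing clinical values are dropped pairwise; pairs with fewer than 4
    complete observations are skipped.
    """
    rows = []
    for mcol in measures.columns:
        for ccol in clinical.columns:
            m = pd.to_numeric(measures[mcol], errors="coerce")
            c = pd.to_numeric(clinical[ccol], errors="coerce")
            ok = m.notna() & c.notna()
            if ok.sum() < 4:
                continue
            rho, p = sps.spearmanr(m[ok], c[ok])
            rows.append(
                {"measure": mcol, "clinical": ccol, "n": int(ok.sum()),
                 "rho": float(rho), "p": float(p)}
            )
    return pd.DataFrame(rows)
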