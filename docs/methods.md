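# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `petnorm`.

## The normative-modelling procedure

A normative model describes, per grey-matter voxel, the distribution of a
PET parametric value (dopamine-synthesis Ki in min⁻¹, or receptor-density
BPND) in a reference cohort of healthy controls as a function of
demographics, and expresses any new subject as a Z-score against that
distribution's posterior predictive. The pipeline runs in a fixed order:

1. harmonize scanner batch effects (fit on controls, apply to everyone);
2. fit one Bayesian linear regression (BLR) per masked voxel on the
   reference cohort;
3. score controls by k-fold cross-validation and patients with the full
   reference-fitted model — patients never influence either the batch
   estimates or the normative parameters;
4. summarize deviations (extreme-deviation fractions, overlap maps, risk
   ratios), run group inference, correlate with symptom scores, and
   classify treatment response.

### Bayesian linear regression per voxel

The model is `y = Xw + ε`, `ε ~ N(0, β⁻¹)`, `w ~ N(0, α⁻¹I)` with design
columns `[1, age, sex(, bmi)]`. Age and BMI are standardized by the
*reference* cohort's mean/SD, which travel with the serialized model so
patient designs are built on the reference scale; sex keeps its {0,1}
coding. The hyperparameters maximize the log marginal likelihood
(evidence); the search is a derivative-free Powell minimization over
`(log α, log β)`, initialized at `(0, log 1/var(y))` so the starting noise
level matches the data scale. The weight posterior is `N(m, A⁻¹)` with
`A = αI + βXᵀX`, `m = βA⁻¹Xᵀy`; all per-voxel solves share one
eigendecomposition of `XᵀX`, making the two-parameter objective O(p) per
evaluation.

A subject's deviation is the posterior-predictive Z-score
`Z = (y* − x*ᵀm)/√(1/β + x*ᵀA⁻¹x*)`. Including the parameter-uncertainty
term `x*ᵀA⁻¹x*` matters at reference sizes of 50–200: without it, Z-scores
of held-out subjects are over-dispersed and extreme-deviation fractions
run systematically above chance.

Degenerate voxels (zero variance) and evidence-optimization failures are
flagged non-converged and carry NaN sentinels; every downstream summary
excludes them from numerator and denominator. Model quality is the
cross-validated explained variance `EXPV = 1 − Var(y − ŷ)/Var(y)`
(population variances; negative when the model is worse than the mean).
Analysis masks keep converged voxels with EXPV above a threshold —
strictly above for the 0 and 0.03 screens, inclusively for the
conservative 0.10 level.

### ComBat harmonization

Parametric empirical-Bayes location/scale adjustment: voxel-wise least
squares for grand mean, covariate effects and per-batch means; residual
variance pooled with weight 1/N; standardized data `z`; per-batch
moment-matched priors `γ ~ N(γ̄, τ̄²)` and `δ² ~ InvGamma(λ, θ)`; the
conditional posterior means are iterated to a fixed point (absolute change
< 1e-4, at most 100 sweeps — the iteration is strongly contracting and in
practice converges to machine precision well within that budget). The
adjustment is `y* = (σ̂/δ*)(z − γ*) + α̂ + Xβ̂`. A single batch yields the
identity; applying to an unseen batch is an error by design — a scanner
the model never saw cannot be adjusted. The implementation is verified at
1e-5 against a frozen output of an independent published reference
implementation on a 40-subject × 100-voxel fixture.

Only the parametric variant is implemented; nonparametric priors,
ComBat-GAM and site-as-random-effect hierarchical models are out of scope.

### Smoothing harmonization

The alternative strategy convolves the target scanner's maps with an
isotropic Gaussian (`FWHM = 2√(2 ln 2) σ ≈ 2.35 σ`), mask-normalized so
edge voxels are not dragged toward zero, and selects the kernel whose
pooled SD best matches the reference scanner (`|SD_target(f) − SD_ref|`
minimized over a candidate grid, ties toward the smaller kernel; the
matching criterion is swappable). Smoothing matches second-order image
statistics but cannot remove additive scanner offsets — the package's
tests demonstrate this directly, and it is why ComBat is the pipeline
default.

## Deviation analytics

Extreme deviations use strict thresholds: Z > 2 (positive), Z < −2
(negative), |Z| > 2 (total), so `pct_tot = pct_pos + pct_neg` is an exact
identity. Under a calibrated Gaussian model the expected per-subject
fractions are the tail masses beyond ±2, ≈ 2.3% per tail and ≈ 4.6%
two-sided — conventionally rounded to 2.5% and 5% as "chance levels".
Overlap maps store the raw per-voxel percentage of subjects with an
extreme deviation; thresholding at chance is a display choice. Risk
ratios pool voxel-subject pairs into one 2×2 table per group
(RR = patient extreme proportion / control extreme proportion, log-Wald
95% CI, +0.5 continuity correction when a cell is empty and flagged as
such). Pooled counting is the default because it yields a single table; a
per-subject-averaged variant is available (`per_subject=True`). The
pooled CI treats voxels as independent, which understates the width under
spatial correlation — at desk scale the generator's noise is voxel-wise
independent, so the interval is honest there.

## Inference

* **Scheirer–Ray–Hare**: all values are ranked with average ties; the rank
  sums of squares are decomposed sequentially (A, then B, then A×B) via
  nested least-squares projections, and `H = SS_effect/(SS_total/(N−1))`
  is referred to χ² with the effect's df. Using the rank MS_total embeds
  the tie correction; with a single-level second factor the statistic is
  exactly the tie-corrected Kruskal–Wallis H.
* **Kruskal–Wallis** effect size: `η² = (H − k + 1)/(N − k)` (negative
  values near the null are legitimate and reported as-is), CI by a
  2000-draw within-group bootstrap.
* **Mann–Whitney**: normal approximation with tie correction and a 0.5
  continuity correction (disable `continuity` to recover the exact
  `H = Z²` equivalence with two-group Kruskal–Wallis); effect size
  `r = |Z|/√N` with bootstrap CI.
* **Permutation GLM**: voxel-wise F for the group factor (or the
  interaction, permuting residuals under the main-effects model), with
  Freedman–Lane residual permutation for nuisance terms, and
  `p_FWE(v) = (1 + #{perm max ≥ obs(v)})/(1 + n_perm)` from the
  permutation distribution of the image-wise maximum. Deterministic under
  a fixed seed.
* **TFCE**: `TFCE(v) = Σ_h extent(v,h)^E · h^H · dh` with E = 0.5, H = 2,
  dh = max/100, 26-connectivity. Inside the permutation GLM the
  enhancement is applied to √F: the standard exponents were calibrated
  for t-scale statistics, and enhancing F = t² over-weights isolated
  high peaks relative to spatially coherent clusters, costing sensitivity.
* **Clusters**: connected components (26-connectivity) of
  {p_FWE < 0.05}, reported at ≥ 50 voxels (the conventional reporting
  floor; configurable), with per-subject mean Z per cluster for post-hoc
  tests.
* **Clinical correlations**: tie-corrected Spearman ρ with pairwise
  deletion of missing scores; pairs with < 4 complete observations are
  skipped.

## Classification

AUC by pair counting with ties at ½ — identical to the normalized
Mann–Whitney U and invariant under monotone transforms. Score orientation
is reported (`higher-score→positive/negative`), never silently flipped,
because responder coding differs across clinical datasets. Correlated
AUCs on the same subjects are compared with DeLong's structural-components
test; a single AUC's Wald CI uses the same component variances.

## The synthetic-data generator

No public multi-site PET cohorts of this kind exist, so the generator is
first-class, tested code that defines the package's study conditions:

`y_sv = μ_v + a_v(age_s − 40) + s_v·sex_s + b_v(bmi_s − 25) + g_{i(s),v}
+ θ_s D_{g(s),v} + d_{i(s)} σ_v ε_sv`, `ε ~ N(0,1)`.

Defaults (all on a Ki-like scale, min⁻¹):

| parameter | default | rationale |
|---|---|---|
| grid | 16×16×16, 2 mm voxels (4096 voxels) | large enough for cluster/TFCE structure, minutes-scale runs; full-resolution grids are a config option |
| baseline μ | 0.010, +0.004 in the striatum | striatal-elevated uptake typical of dopamine-synthesis maps |
| age slope a | −3e-5 /year | with the ~13-year age SD and σ = 1e-3, age explains ~10–12% of variance, matching the modest explained variance of voxel-wise PET models |
| sex offset | 5e-4 | moderate, detectable covariate |
| noise σ | 1e-3 | ~10% of baseline |
| batch effects | shift +8e-4, scale ×1.25 on scanner B | location *and* scale scanner differences, the pattern harmonization must fix |
| deviations θ̄ | FEP 2.5e-3 (striatal +), chronic 2.0e-3 (striatal + with cortical −0.75 weight) | ≈ 2–2.5 noise-SD planted effects: first-episode psychosis as striatal elevation, chronic illness adding a cortical deficit |
| reference size | 50 controls over 2 scanners (30/20) | the recommended minimum reference design: ~50 scans, ≥ 10 controls per scanner |
| response rule | responder iff striatal deviation > 2.5e-3, 10% label flips | deterministic imaging-response coupling degraded by realistic label noise from heterogeneous clinical response definitions |
| PANSS | total = 30 + round(positive part of 25 + 6·θ/σ + N(0,8)), split 30/25/45% into subscales | keeps the scale floor and subscale identity exact, gives a detectable but noisy symptom–deviation correlation |

Groups: HC (θ = 0), FEP, SCZ; each scanner must include at least one
control or generation fails (batch effects would be inestimable). Dataset
labels are case-control per scanner, mirroring multi-dataset study
designs. Identical spec + seed reproduces output bitwise.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: spatial noise correlation and scanner
point-spread differences (noise is voxel-wise independent, so smoothing
harmonization's SD-matching behaves more simply than on real PSF
mismatches, and pooled-RR CIs are narrower than they would be under
spatial correlation); nonlinear covariate effects; non-Gaussian PET noise;
motion and partial-volume artifacts; dataset-specific clinical response
definitions (a single thresholded-deviation rule stands in for four
different criteria); and the high (~56%) non-convergence fraction seen on
real maps, which arises from low-signal voxels the generator does not
produce.

## Validation designs and problem sizes

The repository validates itself on fixed simulation designs, sized to run
in minutes on one CPU:

* **Null calibration** (also what `scripts/acceptance.py` reports):
  two-scanner reference of 200 controls on the 4096-voxel grid,
  ComBat-harmonized, BLR fit, 100 fresh subjects scored with the stored
  models. Mean per-subject extreme fractions land at the Gaussian tail
  masses (~2.3–2.5% positive, ~4.6–5% total).
* **Harmonization contrast**: 50 seeds of a two-scanner phantom with a
  1-σ additive shift; the scanner difference in per-subject mean Z is
  significant before harmonization and after smoothing, and removed by
  ComBat, in ≥ 90% of seeds each.
* **Parameter recovery**: planted BLR weights within 0.1 sup-norm at
  n = 200 in ≥ 95% of seeds; noiseless batch shifts to 1e-6; planted age
  slopes preserved by ComBat within 10% bias over 50 seeds.
* **FWE calibration**: 200 null replicates × 1000 voxels × 500
  permutations; the family-wise error rate at nominal 0.05 stays within
  [0.01, 0.10].
* **Planted-effect pipeline run**: three case-control datasets at the
  patient sizes typical of the real multi-dataset studies (24/20/20
  patients, 48 controls), checking RR > 1 with CI excluding 1, patient
  overlap above control overlap, a group effect on total extreme
  deviations, and striatal mean-Z AUC above 0.5 with CI excluding 0.5.

## Known limitations

* Evidence optimization is per-voxel and independent; no spatial
  regularization or variance smoothing.
* The Wald RR interval and the DeLong normal approximation are
  large-sample constructions; at very small cohorts they can undercover.
* The Scheirer–Ray–Hare decomposition uses sequential sums of squares; in
  unbalanced designs the factor order (group, then dataset) matters, as
  it does in the classical construction.
* Serialization is plain JSON: simple and diff-able, but large models
  (hundreds of thousands of voxels) would warrant a binary format.
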