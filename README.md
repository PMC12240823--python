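# petnorm

Normative modelling of molecular-imaging parametric maps.

PET parametric maps — dopamine-synthesis capacity (Gjedde–Patlak Ki, min⁻¹)
or receptor availability (BPND) — are expensive to acquire, so clinical
studies pool small cohorts from several scanners and sites. `petnorm`
implements the analysis chain that makes such pooled data usable for
individual-level inference:

1. **Harmonization** of scanner/site batch effects, either by parametric
   empirical-Bayes location/scale adjustment (ComBat, with covariate
   effects estimated and preserved) or by Gaussian-kernel smoothing matched
   to a reference scanner.
2. **Voxel-wise normative models**: one Bayesian linear regression per
   grey-matter voxel relates the parametric value to demographics
   (age, sex, optionally BMI) in a healthy reference cohort,

   y = Xw + ε, ε ~ N(0, β⁻¹), w ~ N(0, α⁻¹I),

   with (α, β) set by evidence (type-II maximum likelihood) optimization.
   A subject's per-voxel deviation is the posterior-predictive Z-score

   Z = (y* − x*ᵀm) / √(1/β + x*ᵀA⁻¹x*).

3. **Extreme-deviation analytics**: per-subject summary measures (mean Z,
   % voxels with Z > 2, Z < −2, |Z| > 2), group overlap maps, and pooled
   2×2 risk ratios of extreme-voxel proportions in patients versus
   controls.
4. **Inference**: Scheirer–Ray–Hare two-way ANOVA on ranks,
   Kruskal–Wallis with η², Mann–Whitney with rank effect size r,
   voxel-wise permutation GLM with Freedman–Lane residual permutation,
   max-statistic FWE correction and threshold-free cluster enhancement
   (TFCE), cluster extraction, and Spearman clinical correlations.
5. **Treatment-response classification**: ROC/AUC by pair counting and the
   DeLong test for correlated ROC curves.

Because real multi-site PET cohorts are access-restricted, the package
ships a first-class synthetic-data generator
(`petnorm.simulate`) that emulates their statistical structure —
multi-scanner location/scale batch effects, linear covariate effects,
spatially structured striatal/cortical deviation fields in patient groups,
symptom scores and response labels coupled to deviation magnitude — so
every stage is testable end to end without any download.

## Worked example

```python
import numpy as np
from petnorm import (GeneratorSpec, generate_cohort, fit_combat, apply_combat,
                     NormativeBLR, summary_measures)

# two-scanner reference cohort of healthy controls + FEP patients
spec = GeneratorSpec(n_subjects={("scannerA", "HC"): 30, ("scannerB", "HC"): 20,
                                 ("scannerA", "FEP"): 18}, seed=7)
maps, cohort = generate_cohort(spec)
hc = (cohort["group"] == "HC").to_numpy()

# harmonize: fit on controls only, apply to everyone
combat = fit_combat(maps.subset(np.flatnonzero(hc)), cohort["scanner_id"][hc],
                    cohort[["age", "sex"]][hc], covariate_names=("age", "sex"))
harm = apply_combat(combat, maps, cohort["scanner_id"], cohort[["age", "sex"]])

# voxel-wise normative models on the reference, Z-scores for the patients
model = NormativeBLR(covariates=("age", "sex")).fit(cohort[hc], harm.values[hc])
Z = model.predict_z(cohort[~hc], harm.values[~hc])
print(summary_measures(Z)[["mean_z", "pct_pos", "pct_tot"]].mean().round(2))
```

Output:

```
mean_z     0.05
pct_pos    3.58
pct_tot    6.30
```

The patients average ~3.6% of voxels with Z > 2 and ~6.3% with |Z| > 2 —
above the ~2.5% / ~5% Gaussian chance levels that a calibrated model
yields for held-out healthy subjects — because the generator plants
positive striatal deviations in the FEP group (the excess concentrates in
the ~60-voxel striatal region, where these patients' Z-scores run 2–3
standard deviations high).

The same analysis runs from the command line off a single YAML config:

```bash
petnorm all --out run/ --seed 7      # simulate → harmonize → fit-nm →
                                     # deviate → stats → classify
```

writing NIfTI maps, tidy CSV tables and a manifest with artifact checksums
(re-running the same config reproduces every artifact bitwise).

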