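# gutbraincov

Tools for linking gut-microbial composition to brain structure: a
compositional **balance signature** search against a continuous
phenotype (BMI), **dysbiosis stratification** of the obese group, and
seed-based **voxel-wise structural covariance** analysis of grey-matter
volumes with **TFCE max-statistic permutation inference** — plus a
synthetic-cohort generator that plants the statistical structure the
analysis assumes, so the whole pipeline is testable end to end without
access to cohort data.

The intended users are researchers analysing 16S phylum tables together
with preprocessed (modulated, smoothed, MNI-space) VBM grey-matter maps.

## The statistics at the core

**Balance.** For disjoint taxon sets A and B, the balance of a
composition x is

```
B(x) = c · log( gmean_{a∈A}(x_a) / gmean_{b∈B}(x_b) ),
c = 1 (default) or sqrt(|A||B|/(|A|+|B|)) (ilr convention)
```

It is invariant to per-sample rescaling, so counts and proportions give
identical values. A selbal-style forward search finds the balance most
predictive of BMI: it starts from the best single pair of taxa (by OLS
R²), greedily adds one taxon per step to either side, and uses repeated
k-fold cross-validation with the one-standard-error rule to pick the
signature size and to tabulate selection robustness.

**Stratification.** Obese subjects above the obese-group median of the
fitted balance form the gut-dysbiosis stratum; cognition (Stroop
interference) and mood (PHQ-9) scores are compared between strata by
t-test / ANCOVA.

**Structural covariance.** For each hypothalamic seed (medial,
x = ±4, y = 2, z = −12; lateral, x = ±6, y = −10, z = −10; 2-mm-radius
spheres, bilateral means), every grey-matter voxel is regressed on the
seed value with per-group seed slopes:

```
GM_v = β₀ + covariates + Σ_g 1[g] · slope_{g,v} · seed + ε
```

Covariates (age, sex, global GM volume, the other hypothalamic seed)
are sequentially orthogonalized (Gram-Schmidt, fixed entry order) so
the seed regressor carries only its unique variance. Pairwise contrasts
of the per-group slopes are the seed-by-group interaction t maps.

**Inference.** T maps are enhanced with TFCE
(`Σ_h e_h^E · h^H · dh`, E = 0.5, H = 2, 26-connectivity) and compared
against the permutation distribution of the maximum TFCE statistic
(Freedman-Lane residual exchange, each direction tested separately):
`p_FWE(v) = (1 + #{perm max ≥ TFCE(v)}) / (n_perm + 1)`. Small-volume
correction restricts the null maximum to a-priori spheres (3-mm
subcortical / 5-mm cortical).

## Worked example

```python
import numpy as np
from gutbraincov import (CohortSpec, gen_microbiome, gen_volume_stack,
                         filter_prevalence, replace_zeros,
                         CrossValidatedBalanceSelector, stratify_by_median)

spec = CohortSpec(rng_seed=1)              # 104 subjects, 31 phyla
table, pheno = gen_microbiome(spec)

positive = replace_zeros(filter_prevalence(table, 0.20))
sel = CrossValidatedBalanceSelector(rng_seed=1).fit(
    positive.to_dataframe(), pheno["bmi"].to_numpy())
print(sel.signature_.key(), round(sel.score_, 3))
pheno["balance_value"] = sel.transform(positive.to_dataframe())[:, 0]
pheno = stratify_by_median(pheno)
print(pheno["stratum"].value_counts().to_dict())
print("r =", round(np.corrcoef(pheno.balance_value, pheno.bmi)[0, 1], 3))
```

prints (seed 1):

```
Fibrobacteres+Firmicutes / Aquificae+Bacteroidetes+Chloroflexi+Deferribacteres+Spirochaetes 0.372
{'non-obese': 42, 'obese-dysbiosis': 31, 'obese-no-dysbiosis': 31}
r = 0.61
```

i.e. the search found a seven-phylum balance explaining ~37% of BMI
variance (the cohort was generated with a planted balance calibrated to
r ≈ 0.57), and the 62 obese subjects split 31/31 at their median
balance. The same run through the full pipeline
(`gutbraincov run --cohort <dir>` or `gutbraincov.pipeline.run_pipeline`)
additionally writes the robustness table, stratified phenotypes,
t/TFCE/p-FWE maps (NIfTI), cluster peak tables and group comparisons.

A command line mirrors the stages: `gutbraincov synth | signature |
stratify | run | report`.

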