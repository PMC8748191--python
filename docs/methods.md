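# Methods

This note records the models implemented in `gutbraincov`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Compositional balance model

Microbiome tables are treated as compositions: only ratios carry
information. The balance between disjoint taxon groups A and B is
`c · log(gmean(A)/gmean(B))`. Choices:

* **Log base**: natural log by default (configurable to 2/10). On this
  scale a phylum-level 2-vs-3 balance between dominant and rare gut
  phyla lands in the 5–7 range, the scale on which such signatures are
  conventionally reported.
* **Normalization `c`**: off by default (plain log-ratio of geometric
  means); the ilr coefficient `sqrt(|A||B|/(|A|+|B|))` is available by
  flag. The coefficient only rescales the statistic and never changes
  R², selection paths, or stratification.
* **Zero handling**: zeros are replaced by an additive pseudocount
  (0.5 on counts; 0.5/depth on proportions, default depth 5000) rather
  than Bayesian-multiplicative imputation. This is simple,
  deterministic, idempotent, and documented as a divergence knob;
  for phylum-level tables after a 20% prevalence filter the affected
  cells are few.
* **Prevalence filter**: taxa absent in more than 20% of samples are
  discarded before selection (the conventional cutoff for sparse
  phyla; configurable).

## Forward balance selection

The search maximizes the OLS R² of `response ~ intercept (+covariates)
+ balance`. The first pair is found by exhaustive enumeration of all
ordered taxon pairs; subsequent steps evaluate every remaining taxon on
each side and accept the best addition if it improves R² by at least
`min_improvement` (default 1e-4; inside cross-validation 0.0, so the
path grows to `max_size` for size scoring). Scoring is vectorized
through the covariate-residualized Gram identities, so a full path on a
100 × 30 table costs a few milliseconds.

Deterministic tie-breaks: score first (ties at 1e-10, below any
meaningful R² difference), then the orientation whose balance
correlates positively with the response, then lexicographic taxon
order with the numerator side first.

Cross-validation is 5-fold × 10 repeats by default. Held-out MSE is
computed for every nested signature size along each training-fold path;
the reported size is the smallest whose mean MSE is within one standard
error of the minimum (the conservative convention when the size rule is
otherwise unspecified). Robustness is tabulated as the fraction of CV
fits selecting each taxon and each exact balance at the chosen size.
The reported signature is the full-data path truncated to that size.

## Stratification and group comparisons

Obese subjects are split at the obese-group median of the fitted
balance; values strictly above the median form the dysbiosis stratum.
The subject sitting exactly at the median (odd group sizes) goes to the
no-dysbiosis stratum by default (`ties_to` flips this); the rule is a
convention, stated because the boundary subject is otherwise ambiguous.
Group comparisons use a pooled-variance two-sample t test (Welch
available), or an OLS ANCOVA on the group indicator when covariates
(e.g. age) are requested.

## Structural covariance GLM

Per-subject grey-matter volumes must share one affine; the analysis
mask keeps voxels whose across-subject mean GM exceeds 0.2. Seeds are
spheres at fixed MNI coordinates: centers are snapped to the nearest
voxel center (snaps beyond half a voxel are logged), membership is
voxel-center distance ≤ radius inclusive — a 2-mm radius on a 2-mm grid
gives the center plus its six face neighbors — and bilateral sphere
means are averaged into one regressor (per-hemisphere mode available).

Covariates enter in a fixed order — age, sex, global GM volume (sum of
modulated voxel values × voxel volume, reported in ml), the other
hypothalamic seed, then the seed of interest — and are sequentially
orthogonalized: each column is centered and residualized on all
previously entered columns. The t statistic of the seed's unique
contribution is unchanged by this, but the interaction columns are
built from the purged seed, which is the point: the seed-by-group terms
then carry no variance shared with age, sex, global volume or the other
seed. Sex is coded 0/1; groups are indicator-coded against the
non-obese reference.

The voxel-wise model uses per-group seed-slope columns
(`seed × 1[group]` for every level) rather than a main effect plus
interactions; pairwise slope contrasts are then directly the
interaction t maps, and the per-group slope t maps double as the
within-group covariance maps. Rank and degrees of freedom are computed
per model; singular voxel fits become NaN and are counted in the log.

## TFCE and permutation inference

TFCE integrates `e_h^E · h^H · dh` over thresholds `h = dh, 2dh, …`
with the canonical E = 0.5, H = 2, 26-connectivity, and `dh = max|t|/100`
per map tail. Positive and negative tails are enhanced separately and
recombined with sign. The implementation processes thresholds from the
top down with an incremental union-find over the masked voxel graph,
which is algebraically identical to relabeling the volume at every
threshold (the test suite checks this against a naive relabeling oracle
to 1e-6 and against the isolated-peak closed form h³/3 to 1%) but fast
enough to sit inside a permutation loop.

FWE control uses the null distribution of the maximum TFCE statistic.
The default exchange scheme is Freedman-Lane: the tested 1-df
combination is isolated by an exact reparameterization of the design,
reduced-model residuals are permuted, and the full model is refit (a
simple group-label exchange is available as a fallback). Each
direction of a contrast is tested separately at p < 0.05, matching the
directional reporting convention. `p = (1 + #{perm max ≥ obs})/(n+1)`,
so the smallest attainable p is 1/(n+1); when fewer distinct
permutations exist than requested (tiny n) the scheme enumerates
exhaustively with a warning. Small-volume correction recomputes p
against the per-permutation maxima restricted to an a-priori sphere
(3-mm radius subcortical, 5-mm cortical by convention), which requires
keeping the per-permutation TFCE maps (float32; ~100 MB at 500
permutations on a desk-scale grid).

Default permutation count is 500 (desk scale); 5000 is a flag away and
scales linearly.

## Synthetic cohorts

The generator is the package's test bed: it emulates the *statistical
structure* of a gut-brain cohort, not its biology.

* **Abundances**: per-taxon log-normal intensities closed to
  proportions, optionally multinomially resampled at 5000 reads. The
  planted 2-vs-3 balance uses two dominant and three rare phyla whose
  baseline log-means put the balance near 6.3 with SD ≈ 0.64 while
  keeping the rare taxa above the prevalence filter at 5000 reads
  (expected counts ≈ 3–5). A quarter of the non-planted taxa receive
  structural zeros so the filter has work to do.
* **BMI**: linear in the latent planted balance plus Gaussian noise
  (SD 6 kg/m²). The slope is calibrated from the empirical balance SD
  so the theoretical R² hits a target (0.3249, i.e. r ≈ 0.57, by
  default); the BMI intercept (31 kg/m²) puts roughly 55% of subjects
  over the BMI-30 obesity threshold, approximating a 57/47 design.
  Counts attenuate the observed correlation slightly relative to the
  latent one. Age is weakly negatively coupled to BMI; Stroop and
  PHQ-9 depend linearly on the balance so dysbiosis strata differ.
* **Volumes**: 32×38×32 voxels at 2 mm with MNI (0,0,0) at the central
  voxel (large enough to contain both hypothalamic seeds and disjoint
  target networks); an ellipsoidal GM template at 0.6; per-subject seed
  signals (SD 0.15) injected into the seed spheres; planted network
  regions receiving `slope(group) × seed signal`; age/sex confound
  fields (smooth unit-RMS random fields) and a multiplicative global
  scale factor; voxel noise (SD 0.05); everything smoothed at 4-mm
  FWHM (separable Gaussian, σ = FWHM/2.3548) — desk-scale versus the
  8 mm of real VBM output, keeping planted networks compact on the
  small grid.
* **Slope-balanced networks**: each seed has a contrast region plus a
  mirrored region with complementary group slopes, so every group
  carries the same total seed loading. This reflects covariance
  *reorganization* between groups and keeps the global-GM covariate
  free of group-specific seed signal; on a desk-scale brain an
  unbalanced network otherwise leaks a small diffuse artifact into the
  interaction maps through the global-volume adjustment (in a
  real-sized brain the network-to-global ratio ≈ 1e-4 makes this
  negligible).

What passing tests show: the estimators recover exactly what was
planted under the generator's assumptions (independent lognormal taxa,
linear effects, Gaussian fields, exchangeable errors). What they do not
show: robustness to real-data features such as taxon-taxon
correlations, non-linear BMI effects, registration error, non-Gaussian
GM distributions, or spatially structured physiological noise.

## Known limits

* Signature identifiability is bounded by the effect size: with a
  2-vs-3 balance calibrated to r ≈ 0.57 at n ≈ 104, each rare
  denominator taxon individually carries r ≈ 0.21 against BMI —
  below the expected maximum chance correlation among ~20 null phyla —
  so exact recovery of all five planted taxa happens in only ~30% of
  cohorts (scale-free in the generator's parameters; only r, n, or the
  taxon count change it). The selection frequencies in the robustness
  table, not the point signature, are the reliable readout at this
  effect size.
* The binary-response (AUC) variant of the selection criterion is out
  of scope; the response must be continuous.
* TFCE significance legitimately extends a voxel or two past the
  support of a genuine effect (cluster continuation); specificity
  checks therefore use a 2-voxel margin around planted regions, and
  false-positive control is established by the null calibration test
  instead.
* Permutation p values assume exchangeability under the reduced model;
  heteroscedastic groups would need a different scheme.

## Problem sizes in the test suite

Oracle tests run on 10³–12³ grids with n = 12–40; calibration uses 200
null datasets of 16³ voxels with 500 permutations each; the end-to-end
tests use the default cohort (n = 104, 31 phyla, 32×38×32 voxels, 500
permutations, ~20 s per seed-contrast on one CPU).
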