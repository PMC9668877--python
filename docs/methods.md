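# Methods

This note documents the models, parameter choices and numerical
decisions behind `methnet`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort

The generator emulates a trauma-exposed, all-female urban cohort of
n = 97 (configurable) with four adverse social exposures, covariates,
and 16 fronto-limbic morphometry outcomes.

**Continuous exposure marginals.** Published cohort tables report mean,
SD and range; the generator treats those three jointly as the marginal
specification and calibrates the latent distribution so the *truncated*
draw reproduces them:

- *CTQ total* (mean 40.5, SD 15.4, range 25–93): a shifted gamma
  truncated at the upper bound, with shape ≈ 0.735 and scale ≈ 25.0
  solved by moment matching on closed-form truncated-gamma moments.
  A truncated normal cannot represent this marginal — on [25, 93] its
  attainable SD at mean 40.5 tops out near 14.4, because the
  distribution is strongly right-skewed (mean sits 23% into the range).
  The gamma reproduces mean and SD exactly.
- *TEI* (mean 4.2, SD 2.3, range 0–10.7): truncated normal with latent
  μ ≈ 3.774, σ ≈ 2.764, solved by moment matching (feasible here).
- *Age* (mean 40, SD 12.5, range 19–62): the printed SD slightly
  exceeds what any truncated normal on the printed range can attain
  (the uniform limit gives 12.41). The calibration matches the mean
  exactly and takes the closest attainable SD (≈ 12.4). No smooth
  unimodal law on [19, 62] reaches SD 12.5 at mean 40 except degenerate
  near-power-law shapes, so we accept the 0.7% shortfall.

Moment matching uses `scipy.optimize.fsolve` on closed-form truncated
moments (regularized incomplete gamma functions for the gamma;
`scipy.stats.truncnorm.stats` for the normal), cached per parameter
set. Draws go through the inverse CDF of a uniform variate so that a
Gaussian copula can couple exposures when requested.

**Categorical exposures.** Household income (30/36/34% across
$0–499 / $500–999 / $1000+ per month), education (15/30/55% across
less-than-high-school / high-school-or-GED / beyond), and
employment/disability (33/7/60% employed / disabled / unemployed) are
drawn from their stated simplexes. Exposures are independent by
default; `exposure_correlation` ρ > 0 couples all five through a shared
standard-normal adversity factor (each latent loads √ρ; adverse
categories sit at the high-adversity quantile end). Independence is the
default because recovery tests are cleanest without confounded
exposures; the observed-data correlation structure is not published as
coefficients, so any value would be invented.

**Covariates.** Four genomic-ancestry dimensions are standard normal
(stand-ins for multidimensional-scaling coordinates, which enter
models linearly); intracranial volume is normal (1.4 × 10⁶ ± 1.3 × 10⁵
mm³); a latent standard-normal smoking propensity drives the
smoking-proxy probes. True leukocyte fractions are Dirichlet with mean
(0.58, 0.07, 0.05, 0.05, 0.15, 0.10) over granulocytes, monocytes, B,
NK, CD4T, CD8T and concentration 60 — typical adult whole-blood
composition with realistic inter-individual spread.

**Morphometry.** The 16 outcomes are bilateral-average hippocampus and
amygdala volumes plus SA and CT of seven Desikan frontal subregions
(frontal pole, medial/lateral orbitofrontal, superior frontal, rostral
middle frontal, rostral/caudal anterior cingulate), with typical adult
means/SDs as defaults. A planted standardized effect vector β produces
`y_std = Σ βₜ xₜ + √(1 − Σ βₜ² var(xₜ)) ε`, then `y = mean + sd·y_std`:
the residual variance is shrunk so that planted standardized
coefficients and the marginal SD are both *exact*, rather than adding
unit-variance noise and rescaling (which would attenuate every planted
effect by 1/√(1+Σβ²) and make recovery tests biased by construction).

**Methylome.** Probe M-values follow a factor model on top of a
cell-composition baseline:

    M_ps = logit2(Σ_c w_sc R_cp) + λ_p f_m(s) + Σ_cov γ_p x_s + ε_ps

where `R` is a synthetic six-cell reference (20% of probes carry
cell-discriminating offsets, SD 1.5 M-units), `w_s` the sample's true
fractions, `λ_p ~ ±U(0.7, 1)` module loadings, `f_m` the module latent
factor (standardized to exact unit sample variance), `γ_p` sparse
covariate effects (default: age affects 20% of probes, SD 0.3 M-units
per SD of age), plus 26 smoking-proxy probes (effects SD 0.4 per SD of
the smoking latent) and i.i.d. probe noise (default SD 1/3, i.e. a
latent/noise ratio of 3). Betas are the inverse logit2. Annotation
assigns autosomes to planted probes; 3% of background probes go to
chrX/Y, 2% are flagged cross-reactive, and 50% of background probes
pass the blood–brain correlation gate (planted probes always pass, so
filtering does not silently destroy the signal under study; the
real-data pass rate is far lower, but a desk-scale universe must keep
enough probes for network analysis).

**Planted mediation.** For the designated module,
`f = a·std(x) + √(1−a²) ε`, and the outcome is rebuilt as
`y_std = b·f + c′·std(x) + √(1 − b² − c′² − 2abc′)·y_std_old`, so on
the standardized analysis scale the path coefficients are exact and the
planted total effect per SD of exposure is identically `a·b + c′`. The
variance-preserving form (rather than literally adding `b·f`) keeps
the outcome's configured marginal SD and makes the planted effects
recoverable without attenuation.

**What the generator does not emulate.** Raw array intensities, batch
and chip effects, probe-type chemistry differences, genomic
autocorrelation of methylation, realistic blood–brain correlation
structure, and exposure–covariate confounding (unless switched on).
Passing tests therefore demonstrate the *statistical machinery* —
filtering, deconvolution, network recovery, FDR accounting, mediation
inference — under a faithful factor-model abstraction, not robustness
to array artefacts.

## Pre-processing

- Beta → M uses ε = 10⁻⁶ boundary clipping: keeps M finite without
  distorting interior values; the inverse is exact on the interior.
- The probe filter removes chrX/Y, `rs`-prefixed and cross-reactive
  probes, then keeps probes with blood–brain correlation p < 0.05. It
  preserves input order and is idempotent.
- Cell deconvolution solves, per sample, nonnegative least squares of
  the sample's betas on the six reference profiles with Σw ≤ 1 — an
  NNLS warm start polished by SLSQP when the simplex constraint binds.
  In the interior this equals the classical quadratic-programming
  formulation of reference-based deconvolution.
- The smoking score is Σᵢ effectᵢ·βᵢ over whichever scoring probes are
  present (computed on the beta scale, matching how EWAS effect sizes
  for smoking are reported); missing probes are logged, zero overlap is
  an error.
- Residualization fits per-probe OLS on intercept, age, five cell
  fractions (granulocytes dropped as the compositional complement),
  four ancestry dimensions and the smoking score, and keeps residuals.
  Employment enters downstream models only, not the residualization
  design. Missing values are disallowed after validation; all
  downstream algebra assumes complete matrices.
- Quantile normalization (optional stage) maps each sample to the mean
  order statistics; ties receive the mean of the order statistics they
  span via average ranks.

## Network construction

- Unsigned adjacency `|r|^power` with Pearson correlation across
  samples — both defaults of the weighted correlation-network
  framework; a signed variant sits behind a flag.
- The scale-free fit discretizes connectivity into 10 equal-width bins
  and regresses log10 bin frequency on log10 mean connectivity over
  nonempty bins (≥ 3 required), reporting both the signed,
  zero-truncated R² and its degrees-of-freedom-adjusted version; the
  scan gates on the adjusted statistic by default and falls back to the
  argmax power (flagged) when no candidate passes. On planted-module
  topologies the background connectivity collapses toward zero and the
  fit occupies too few bins to be meaningful, so recovery experiments
  fix power 6 instead of consuming the fallback.
- TOM: `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`,
  `l = A²`; dissimilarity `1 − TOM`, clipped to [0, 1], zero diagonal.
- Clustering: average-linkage on TOM dissimilarity with a *static* cut
  — fully specifiable and deterministic, unlike the dynamic hybrid
  cut. The default cut height is 0.95 of the maximum merge height.
  This default is deliberate: with ~100 samples, chance correlations
  among thousands of background probes reach |r| ≈ 0.3–0.5, which maps
  to TOM dissimilarities of ~0.985–0.999 against genuine modules —
  a cut at 0.995 of the maximum glues such probes onto modules, while
  genuine within-module merges sit far lower (≲ 0.7 at meaningful
  signal-to-noise). Clusters below `min_size` (default 10) are
  unassigned (label 0); survivors are relabeled 1..K by decreasing
  size, with color-name aliases for reporting.
- Eigengenes: probes z-scored across samples; the ME is the leading
  left singular vector of the samples × probes block, sign-aligned to
  correlate nonnegatively with the module's mean probe profile (PCs
  are sign-ambiguous and downstream mediation signs must reproduce),
  scaled to unit variance; variance explained is s₁²/Σs².

## Screening and FDR

Continuous dependent and independent variables are standardized before
fitting, so coefficients are standardized effects; category indicators
stay 0/1 with the least-adverse category as reference (income $1000+,
education beyond high school, employed). Arm A fits all four ASE terms
jointly per outcome with ancestry, age and employment as covariates and
ICV added only for the two subcortical volumes; overall CT/SA are
deliberately not covariates. Arm B uses employment as the only
covariate (the other confounders were removed by residualization).
Arm C enters one ME per model with the Arm A covariate set.

The BH procedure is the standard step-up rule: sort p ascending, find
the largest k with `p_(k) ≤ (k/m)·q`, flag everything at or below
`p_(k)`; ties share flags. A literal per-rank variant without the
step-up closure is available behind a flag for sensitivity analysis.
Families follow the published accounting: 64 tests for Arm A
(16 outcomes × 4 ASE terms), one test per module per exposure in Arm B,
the gated (ME, outcome) pairs in Arm C, and 2 × module-size for
probe-wise mediation (IDE and DE p-values jointly). Every family's m
and q are logged.

## Mediation

Mediator model `m ~ x + covariates` and outcome model
`y ~ x + m + covariates` are fit by OLS with no exposure–mediator
interaction — the product-of-coefficients decomposition `IDE = a·b·Δ`,
`DE = c′·Δ`, `TE = IDE + DE` is exact only in that case. Coefficients
are drawn n_draws = 10,000 times (default) from the multivariate normal
with mean at the estimates and the estimated coefficient covariance,
independently per model; point estimates are draw means, intervals are
2.5/97.5 percentiles, p-values are twice the smaller zero-crossing
proportion (no continuity correction). Per-draw and point-estimate
additivity holds to machine precision and is enforced by the record
type.

The default exposure contrast Δ spans the observed minimum to maximum
of the exposure: published total effects of this design are an order of
magnitude larger than the per-SD slope, consistent with a
highest-versus-lowest-exposure contrast (≈ 4.4 SD for a CTQ-like
marginal), not a 1-SD contrast. A unit contrast is available via
`contrast="sd"`. Mediator and outcome models reuse the Arm B and Arm C
covariate sets respectively, for consistency with the screens that
gate the candidates. Classification: *full* if p_TE < α and p_IDE < α
while p_DE ≥ α; *partial* if all three < α; *none* otherwise.
Proportion mediated is the point-estimate ratio IDE/TE (undefined and
flagged at TE = 0); displayed percentages are integer-rounded, and
because the ratio is reported unrounded internally, neighboring
roundings (e.g. 34 vs 35%) are both derivable from the same record.

## Enrichment

The probe-wise screen is a vectorized OLS over all probes with the four
ASEs plus employment in the design; the exposure of interest's p-value
per probe feeds gene aggregation. Gene p = 1 − (1 − min pᵢ)^k over the
gene's k probes (Šidák), correcting the probes-per-gene bias of raw
min-p. Over-representation uses the hypergeometric tail of the overlap
between nominally significant genes (α = 0.05) and each set, with the
measured-gene universe as background; sets outside 25–1,000 measured
genes are excluded (removing uninformative high-level terms); BH across
tested sets at q = 0.10. This is the over-representation mode of
probe-aware gene-set testing; a rank-based variant is future work.
Probe→gene mapping uses the single gene symbol in the annotation;
multi-gene probes are out of scope.

## Orchestration and reproducibility

The CLI runs stages `simulate | preprocess | network | screen |
mediate | enrich | all` against an output directory; every stage
appends a manifest entry (config hash, master seed, stage seed, package
version). Stage seeds derive from SHA-256 of the master seed and stage
name, so stages are independently reproducible and re-running a stage
with the same inputs is byte-identical. All tables are TSV; gene sets
are GMT; configuration round-trips through YAML.

## Problem sizes

Tests and the acceptance script run at desk scale by design: cohorts of
97 (study size) to 100,000 (marginal calibration), methylomes of
300–2,000 probes, mediation recovery at n = 5,000 with 500 replicates
of 2,000 Monte Carlo draws, and 10,000-family FDR oracle comparisons.
These sizes make every property testable in seconds while keeping the
operating regime (p ≫ n for the network stage) faithful.

## Known limitations

- The static tree cut requires a sensible cut height; very heterogeneous
  module tightness would favor the dynamic hybrid cut, which is out of
  scope.
- The soft-threshold scan is meaningful on smoothly varying connectivity
  distributions; on sharply bimodal synthetic topologies it falls back
  (flagged) and a fixed power is preferable.
- Quasi-Bayesian draws treat the two model fits as independent, which
  is standard but ignores cross-model correlation induced by sharing
  data; coverage is nominal in the tested regimes.
- The deconvolution reference is synthetic; absolute cell-fraction
  accuracy on real arrays depends on reference quality.
- No sensitivity analysis for sequential ignorability: mediation here
  is statistical, not causal, exactly as in the design it implements.
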