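# methnet

Co-methylation network and causal-mediation analysis linking adverse
social exposures (ASEs) to fronto-limbic brain morphometry through
blood DNA methylation.

## The problem

Low income, low educational attainment, and childhood or adult trauma
burden are associated with measurable differences in brain structure —
gray matter volume of the hippocampus and amygdala, and surface area
(SA) / cortical thickness (CT) of frontal-cortex subregions — that are
regarded as endophenotypes of stress-related psychiatric illness. DNA
methylation (5mC) measured in blood is a candidate mechanism for the
biological embedding of such exposures, and a practical peripheral proxy
when brain tissue is inaccessible. `methnet` implements, as a tested and
reusable pipeline, the analysis chain that asks: *do clusters of
co-methylated blood CpG probes statistically mediate the association
between an adverse exposure and a brain morphometry measure?*

Because cohorts of this kind pair restricted neuroimaging data with
array methylation, the package ships a first-class synthetic-cohort
generator that emulates the study conditions — published phenotype
marginals, an EPIC-like probe universe with planted co-methylated
modules, leukocyte-composition and smoking effects, and a planted
exposure → module → outcome mediation path — so every downstream stage
is testable against known ground truth.

## The method

1. **Pre-processing** (`methnet.preprocess`). Beta values are
   logit2-transformed to M-values, `M = log2(β/(1−β))`; probes on
   chrX/chrY, `rs`-prefixed probes, cross-reactive probes and probes
   without nominal blood–brain correlation (p ≥ 0.05) are removed.
   Leukocyte fractions (granulocytes, monocytes, B, NK, CD4T, CD8T) are
   estimated by reference-based deconvolution (constrained projection,
   w ≥ 0, Σw ≤ 1); a polyepigenetic smoking score is a weighted sum of
   scoring-probe betas. Each probe's M-values are residualized on age,
   five cell fractions, genomic ancestry and the smoking score.
2. **Co-methylation network** (`methnet.network`). Unsigned weighted
   adjacency `a_ij = |cor(p_i, p_j)|^power`, with the power chosen as
   the lowest at which the connectivity distribution fits scale-free
   topology with R² > 0.90; topological-overlap dissimilarity
   `1 − TOM`; average-linkage hierarchical clustering with a static tree
   cut and minimum module size 10; the module eigengene (ME) is the
   first principal component of the module's standardized probes.
3. **Three-arm screen** (`methnet.screening`). Arm A: morphometry ~
   ASEs + covariates (16 outcomes × 4 ASE terms = 64 tests). Arm B:
   ME ~ ASEs + employment. Arm C: morphometry ~ ME + covariates.
   Continuous variables standardized; Benjamini–Hochberg FDR control at
   q = 0.10 per arm; nominal gates (α = 0.05) define mediation
   candidates.
4. **Mediation** (`methnet.mediation`). For each gated (exposure, ME,
   outcome) triple, quasi-Bayesian Monte Carlo mediation: OLS mediator
   and outcome models, 10,000 coefficient draws from their estimated
   sampling distributions, per-draw `IDE = a·b·Δ`, `DE = c′·Δ`,
   `TE = IDE + DE` (exact additivity). A mediator is *full* when TE and
   IDE are distinguishable from zero but DE is not, *partial* when all
   three are. Probes of full-mediator modules get probe-wise follow-up
   with BH over the joint IDE/DE family.
5. **Enrichment** (`methnet.enrichment`). Probe-wise exposure EWAS on
   residualized M-values, Šidák-corrected min-p aggregation to genes,
   and hypergeometric over-representation across gene sets of 25–1,000
   measured genes with BH control.

## Worked example

```python
from methnet import synthetic as syn, preprocess as pp, network as net
from methnet import screening as scr, mediation as med
import pandas as pd

pheno, truth = syn.simulate_phenotypes(syn.CohortConfig(seed=1))
sim = syn.simulate_methylome(pheno, syn.MethylomeConfig(seed=2), truth)

cells = pp.estimate_cell_proportions(sim.beta, sim.cell_reference)
smoking = pp.smoking_score(sim.beta, sim.smoking_effects)
m = pp.filter_probes(pp.beta_to_m(sim.beta), sim.annotation)
resid = pp.residualize(m, pp.build_covariate_design(sim.phenotypes, cells, smoking))

scan, modules = net.build_network_modules(resid, power=6)

arm_a = scr.fit_arm_a(sim.phenotypes)
arm_b = scr.fit_arm_b(modules.eigengenes, sim.phenotypes)
outs = sorted({r.outcome for r in arm_a if r.p < 0.05})
mes = sorted({r.outcome for r in arm_b if r.p < 0.05})
arm_c = scr.fit_arm_c(modules.eigengenes, sim.phenotypes,
                      pairs=[(me, o) for me in mes for o in outs])
cands = scr.gate_candidates(arm_a, arm_b, arm_c)
recs = med.mediate_candidates(cands, modules.eigengenes, sim.phenotypes,
                              n_draws=10_000, seed=3)
```

Output:

```
cohort: 97 participants; CTQ mean 39.0 (SD 14.9)
retained 1014 of 2000 probes after filtering
8 co-methylation modules at soft threshold 6
Arm A: 64 tests, 2 outcome(s) nominally ASE-associated
1 gated candidate triple(s)
ctq -> ME1 -> rmfg_sa: IDE -0.798 (p=0.000), DE -0.489 (p=0.222),
    TE -1.287 (p=0.003) -> full, 62% mediated
planted truth: a=0.35, b=-0.45, c'=-0.1 (TE per SD = -0.258)
```

Reading the numbers: the generator planted a path from childhood trauma
burden (CTQ) through module 1 to rostral middle frontal gyrus surface
area. At n = 97 the pipeline recovers exactly that triple through the
nominal gates, and the mediation stage classifies the module eigengene
as a full mediator: the indirect effect (−0.80 SD of RMFG SA across the
observed CTQ range) is distinguishable from zero while the direct
effect is not, and IDE + DE = TE exactly. The effects are on the
standardized outcome scale with the exposure contrast spanning its
observed range, so point estimates at n = 97 are noisy around the
planted total effect (−0.258 per SD of CTQ, ≈ −1.1 over the range).

A command-line driver runs the same chain stage by stage:

```sh
methnet all --outdir out --seed 3
```

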