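# amylasekit

Tools for the systems-biology analysis of the relationship between
salivary/pancreatic amylase and adiposity: droplet digital PCR (ddPCR)
copy-number calling for the multi-allelic *AMY1A*/*AMY2A* loci,
covariate-adjusted association of amylase measures with metabolic traits,
bidirectional Mendelian randomization (MR) between BMI and plasma amylase
enzymatic activity, fixed-effect meta-analysis across studies, and a
BMI-linked metabolite screen. A synthetic-cohort generator reproduces the
statistical structure of the epidemiological data (multi-allelic copy numbers
with parity coupling, copy-number-driven enzymatic activities, genetic
instruments for BMI, left-censored metabolites), so every stage is testable
offline and parameter recovery can be verified under known truth.

The intended users are statistical geneticists and epidemiologists who want a
reproducible, scriptable implementation of this analysis family, either on
synthetic cohorts or on their own flat-file exports with matching columns.

## Methods at a glance

**ddPCR copy number.** Template molecules partition into droplets with Poisson
occupancy, so each channel's mean is `lambda = -ln(1 - n_pos/n_total)` and the
diploid copy number against a two-copy reference assay is
`CN = 2 * lambda_target / lambda_ref`. Wells with fewer than 7000 accepted
droplets fail QC and are dropped. Integer calls use nearest-integer rounding
with ties to even.

**Trait association.** Linear (or logistic) regression of the trait on the
amylase exposure, adjusted for age, sex, BMI, daily alcohol, smoking and two
ancestry principal components; right-skewed traits are ln-transformed.
AMY1 activity is derived as total amylase minus AMY2 activity, and analyses
keep only individuals within the assay normal ranges (AMY2 13-53 U/L, total
29-99 U/L).

**Mendelian randomization.** Per-variant Wald ratios
`beta_outcome / beta_exposure` with the first-order standard error
`se_outcome / |beta_exposure|`, pooled by inverse-variance weighting
(`w_i = 1/se_i^2`); two-stage least squares instrumented by the unweighted
genetic risk score (sum of BMI-increasing alleles over 83 SNPs); MR-Egger
weighted regression whose intercept tests directional pleiotropy; instrument
discovery by a Bonferroni-controlled per-SNP activity scan
(`P < 0.05 / n_tests`) plus a residual-association validity rule (a candidate
must show no outcome association once the exposure is adjusted for).

**Meta-analysis.** Fixed-effect inverse-variance pooling with the pooled-z
P value and Cochran's Q heterogeneity test; odds-ratio inputs are pooled on
the log-OR scale with `se = (ln hi - ln lo) / (2 * 1.96)`.

## Worked example

```python
from amylasekit.simulate import (SimulationConfig, generate_cohort,
                                 generate_snp_truth, generate_droplet_wells)
from amylasekit.ddpcr import CopyNumberCaller, rank_correlation
from amylasekit.meta import StudyEstimate, fixed_effect_meta
from amylasekit.mr import InstrumentSet, build_grs, tsls

cfg = SimulationConfig(n_individuals=4000, causal_scenario="bmi_to_amy", seed=1)
cohort = generate_cohort(cfg)
truth = generate_snp_truth(cfg)

wells = generate_droplet_wells(cohort, droplets_per_well=20000, ref_lambda=0.5, seed=1)
calls = CopyNumberCaller().transform(wells)
exact = (calls.set_index("sample_id").loc[cohort["id"], "cn_integer"].to_numpy()
         == cohort["cn_amy1a"].to_numpy()).mean()
print(f"exact integer CN calls: {100 * exact:.2f}%")

rho2, p = rank_correlation(cohort["cn_amy1a"], cohort["amy1_activity"])
print(f"Spearman rho^2(CN, AMY1 activity) = {rho2:.3f} (P = {p:.2e})")

snps = truth["snp_id"].tolist()
inst = InstrumentSet(snp_ids=snps, grs_weights={s: 1 for s in snps})
work = cohort.assign(grs=build_grs(cohort[snps], inst))
est = tsls(work, exposure="bmi", outcome="amy1_activity", instrument="grs")
print(f"TSLS BMI->AMY1: beta = {est.beta_causal:.2f} +/- {est.se:.2f} IU/L per kg/m^2 "
      f"(P = {est.p:.3g})")

pooled = fixed_effect_meta([StudyEstimate("discovery", -2.36, 0.39),
                            StudyEstimate("replication", -2.31, 0.85)])
print(f"pooled SNP effect: {pooled.beta_pooled:.2f} +/- {pooled.se_pooled:.2f} "
      f"(P = {pooled.p_pooled:.2g}, Q = {pooled.q:.3f}, P_het = {pooled.p_het:.2f})")
```

Output:

```
exact integer CN calls: 99.85%
Spearman rho^2(CN, AMY1 activity) = 0.340 (P = 0.00e+00)
TSLS BMI->AMY1: beta = -3.44 +/- 0.49 IU/L per kg/m^2 (P = 1.68e-12)
pooled SNP effect: -2.35 +/- 0.35 (P = 3.3e-11, Q = 0.003, P_het = 0.96)
```

The first two lines validate the measurement layer: single 20,000-droplet
wells recover the true integer copy number almost always, and the calibrated
cohort reproduces the target rank correlation between *AMY1A* copies and AMY1
activity. The TSLS line estimates the simulated causal effect of BMI on AMY1
activity (negative, as injected). The last line pools a discovery and a
replication estimate of an activity SNP into a single fixed-effect row with
no evidence of heterogeneity.

A command-line interface mirrors the library
(`amylasekit simulate | cnv-call | assoc | mr... | meta | metabolites | run-all`);
`amylasekit run-all --n 2000 --seed 1 --out-dir out/` writes every stage's
table plus a manifest recording the configuration hash, seed, row counts and
all exclusions.

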