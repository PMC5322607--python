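# Methods

This note documents the statistical model behind each module, the generator's
structural equations and calibration, the numerical conventions, and the known
limitations — in particular what passing tests on synthetic cohorts do and do
not establish about real data.

## The synthetic cohort model

The generator (`amylasekit.simulate`) draws each cohort from a recursive
structural equation system. Variables are generated in causal order, so every
downstream estimator can be checked against known truth.

**Copy numbers.** *AMY1A* and *AMY2A* diploid copy numbers are integers on
[1, 20]. A per-individual parity bit (even with probability
`parity_even_fraction`, default 0.6) reproduces the even-copy excess seen in
digital-PCR data; the *AMY2A* parity equals the *AMY1A* parity with
probability `parity_coupling` (default 0.95 — the coupling strength is not
quantified in published data beyond "nearly always", so 0.95 is a free
parameter chosen to make discordance rare but observable at cohort size).
Conditional on parity, the copy number is a latent normal draw rounded to the
nearest integer of that parity; because the parity grid has spacing 2, the
rounding adds variance 1/3, and the latent SD is deflated by that amount so
the realized SD matches the configured target (mean 7.0, SD 2.6 for *AMY1A*;
mean 2.5, SD 1.3 for *AMY2A*). Clipping to [1, 20] is a per-mille effect at
these settings.

**Genotypes.** `n_snps` (default 83) biallelic SNPs in Hardy-Weinberg
proportions with MAF uniform on `maf_range` (default 0.05-0.5). Per-allele
BMI effects are uniform on 0.05-0.25 kg/m^2 — a typical GWAS effect scale
that gives the 83-SNP score a first-stage F far above the weak-instrument
threshold at n of a few thousand. No linkage disequilibrium, pedigree
structure or genotyping error is simulated.

**BMI.** On the raw kg/m^2 scale,

    bmi = 25.2 + 0.03 (age - 47) + 0.8 (sex - 1/2) + sum_j beta_j (g_j - 2 p_j)
          + u + a2b * (amy1_base - mean) + eps,

with `u ~ N(0, 1)` an unmeasured disturbance and `eps` sized so the total BMI
variance is 16 (SD 4 kg/m^2). The structural equations are Gaussian on the
raw BMI scale rather than the log scale: this makes the Wald-ratio and TSLS
estimands exactly equal to the injected kg/m^2 effects, while `log(BMI)` of a
tight Gaussian remains close enough to linear for the ln-transformed
association models. The reverse-causal term `a2b` (activity to BMI, default
-0.05 kg/m^2 per IU/L) is active in the `amy_to_bmi` and `bidirectional`
scenarios and uses the pre-BMI component of AMY1 activity, making the system
acyclic while carrying both directions of effect.

**Activities.** Each activity has a copy-number-driven base
(`amy1_base = -4 + 7 * CN1 + N(0, 8)`, `amy2_base = 20 + 5 * CN2 + N(0, 6)`,
IU/L), plus the scenario-dependent BMI effect
(`b2a1 = -4.15`, `b2a2 = -2.53` IU/L per kg/m^2 by default), plus calibrated
noise. The noise SD is found by bisection so that the realized squared
Spearman correlation between copy number and activity equals the target
(0.34 for AMY1, 0.12 for AMY2, tolerance well inside +/-0.05); the search
reuses one fixed standard-normal draw so the objective is deterministic and
monotone. Activities are floored at 0.1 IU/L. Two consequences are worth
stating plainly: (i) honouring simultaneously a causal BMI effect of
-4.15 IU/L per kg/m^2, a BMI SD of 4 and a rank correlation of 0.34 forces
the synthetic AMY1 activity SD to ~30 IU/L, larger than clinical assays
report, so a larger fraction of synthetic individuals falls outside the
normal-range filter (AMY2 13-53 U/L, total 29-99 U/L) than in a real cohort;
(ii) the floor truncates ~8-10% of AMY1 values, which mildly attenuates
SNP-to-activity coefficients (the IVW recovery suites show a ~5% attenuation
of the injected -4.15, well inside the 15% recovery band). The *AMY2A* slope
of 5 IU/L per copy is the smallest round value for which the 0.12 correlation
target stays reachable once the BMI-driven variance is in place.

**Follow-up.** A configurable fraction (default 0.75) has 9-year follow-up
values: `log(bmi_fu) = log(bmi) + 0.02 + c * (amy1 - mean) + N(0, 0.08)` with
`c = beta_amy1_on_bmi_change` (default -0.006 per IU/L), and activities drift
by `-0.20` (AMY1) / `-0.18` (AMY2) IU/L per baseline kg/m^2 plus noise.

**Metabolites.** 36 panel metabolites, in arbitrary units, are
`5 + gamma_m * z(log BMI) + N(0, 1)` with `|gamma_m| = 0.35` and a fixed sign
pattern (most positive, a fixed subset negative). Lactate additionally
receives a direct AMY1-activity effect (default 0.012 units per IU/L). The
default is sized so the lactate signal remains detectable (z about 4-5) in
the *unadjusted* screen at the metabonomics sample size of ~700: because
activity and BMI are negatively coupled while BMI raises lactate, the
BMI-mediated path partially cancels the direct one, and a materially smaller
direct effect would make the unadjusted screen blind to it — the generator is
meant to reproduce a BMI-independent lactate signal visible both with and
without BMI adjustment. Missingness is left-censoring: the lowest
`missing_rate_metabolites` fraction (default 3%, capped at 5%) of each
metabolite becomes missing, which is exactly the mechanism minimum-value
imputation assumes.

**Case-control studies.** `generate_case_control` draws copy numbers from the
same parity model and assigns case status by a logistic model in copy number
(configurable per-copy OR, default 0.94), age and sex, sampling until the
case and control quotas fill.

Identical `(config, seed)` reproduce byte-identical tables; all randomness
flows through named `numpy` generator streams keyed on the seed.

### What the generator does *not* emulate

Linkage disequilibrium and proxy-instrument substitution, genotyping error,
assay batch effects, non-Gaussian trait tails, informative missingness beyond
left-censoring, more than one follow-up visit, and realistic activity
variance (see above). Parameter-recovery results on these cohorts therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to real-data violations of those assumptions.

## Copy-number calling

`lambda_c = -ln(1 - positives_c / droplets)` per channel;
`CN = 2 * lambda_target / lambda_ref`. Integer calls round to the nearest
integer with ties to even (the rounding rule is a package convention; vendor
software does not publish one). Wells under 7000 droplets fail QC and are
dropped, not imputed. A fully positive channel (occupancy unbounded) and a
zero-positive reference channel are reported as errors with the sample id.
A delta-method 95% CI on the continuous CN is available
(`estimate_copy_number(..., with_ci=True)`) but is not propagated into
downstream regressions, which treat the integer CN as known.

Precision is limited by Poisson-occupancy information. At 20,000 droplets and
reference occupancy 0.5, the CN standard error grows from ~0.02 at 2 copies
to ~0.10 at 7, ~0.18 at 12 and ~0.41 at 20 copies as the target channel
saturates; per-well exact integer calls are therefore near-certain through
~12 copies and progressively less certain above, with no bias. Averaged over
the cohort's copy-number distribution (mean 7, SD 2.6) the exact-call rate
exceeds 99%. Resolving the extreme tail with comparable certainty requires
more droplets or replicate wells, which are out of scope here (inputs are
single classified wells).

## Association models

Design matrices code sex 0/1, smoking as unordered indicator columns
(reference level dropped), alcohol continuous in g/day. All "logarithmically
transformed" traits use the natural log; since effects are reported per
unchanged exposure unit, the base only rescales the trait axis. Estimation is
complete-case within each model; subgroup rules (glucose traits in
non-diabetics, lipids off lipid-lowering drugs, blood pressure off
anti-hypertensives) are applied before fitting and counted. Linear-model P
values are t-based; logistic effects report the Wald-normal P and
`exp(beta +/- 1.96 se)` as the OR CI. The 9-year change model regresses the
follow-up value on the baseline predictor with the baseline value as a
covariate — equivalent to a change-score model with baseline adjustment up to
the baseline coefficient, and the better-posed of the two forms.

## Mendelian randomization

The Wald-ratio SE is first-order (`se_out / |beta_exp|`), deliberately
ignoring the denominator's sampling error; the full second-order delta SE is
available behind `second_order_se=True` but is not the default, because the
exposure effects come from a much larger external GWAS and are treated as
fixed. IVW pooling and its P use the pooled-z normal approximation. TSLS
reports the standard IV variance with stage-2 residuals computed against the
observed (not fitted) exposure; the default covariate set for TSLS is age,
sex and the two ancestry PCs in both stages (an assumption — the adjustment
set is configurable). The first-stage F is always computed and F < 10 raises
a warning. Egger regression orients exposure effects positive, weights by
`1/se_out^2`, and reports the intercept with a t-based P on k - 2 df.
Harmonization flips the outcome effect sign when the two sources report
swapped alleles; strand-ambiguous (A/T, C/G) pairs are aligned by allele name
only and warn. The per-SNP scans run as a single residualized
(Frisch-Waugh-Lovell) pass, which is numerically identical to per-SNP full
OLS and keeps replicate suites fast; monomorphic SNPs are reported as NaN
rather than failing the scan. Instrument validity uses two rules: Bonferroni
retention at `0.05 / n_tests`, and rejection of any candidate whose residual
association with the outcome (given the exposure and covariates) has
P <= 0.05.

## Meta-analysis

Fixed-effect inverse-variance pooling; `Q = sum w_i (beta_i - beta_pooled)^2`
on chi-square k-1 df. The pooled P uses the pooled z, which is the weighted
inverse-normal combination with weights proportional to 1/se; a
sample-size-weighted Stouffer variant sits behind `p_method="stouffer"`.
Odds-ratio rows convert printed CIs to log-scale SEs assuming symmetric
normal intervals with z = 1.96; since printed ORs are rounded to two
decimals, reconstructed heterogeneity statistics are only trustworthy to that
precision (the pooled OR and CI are stable, the heterogeneity P can shift in
the second decimal).

## Metabolite screen

Minimum-value imputation replaces each metabolite's missing entries with its
smallest detected value — idempotent, extrema-preserving, and matched to the
left-censoring mechanism of the generator. The screen fits one adjusted
linear model per metabolite (shared design, multi-response residualized
solve), with and without BMI in the adjustment, and reports sign concordance
between the exposure effect and the metabolite's own BMI effect. No
multiple-testing correction is applied to the primary P values (nominal
reporting); a Bonferroni column over the 36-metabolite panel is emitted
alongside. Values are analysed untransformed by default (panel units are
arbitrary); a log option exists.

## Replicate suites and problem sizes

Monte-Carlo checks use explicit sizes chosen to give comfortable margins at
modest runtime: recovery of the injected BMI-to-activity effect uses 200
replicate cohorts of n = 4000 (IVW) and n = 3673 (TSLS) in the test suite and
60 in the acceptance script; Egger calibration uses 200 summary-level
replicates of 83 instruments; null-calibration checks use 120 replicate
cohorts; the per-copy OR recovery uses the case-control sizes 785/712.
Across these, the means recover injected values within the stated bands
(15% IVW, 25% TSLS, 30% change model) and null P values pass
Kolmogorov-Smirnov uniformity at the 1% level.

## Known limitations

* The ddPCR caller's exact-call guarantee degrades above ~12 copies per well
  (information bound, not implementation).
* TSLS covariates and the GRS weighting (unweighted allele count) are
  conventions; weighted scores and alternative adjustment sets would change
  estimates on real data.
* The generator's activity variance is larger than clinical, so normal-range
  exclusion rates are not representative.
* LD-aware pruning, weighted-median/mode MR estimators, multivariable MR and
  random-effects meta-analysis are intentionally absent.
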