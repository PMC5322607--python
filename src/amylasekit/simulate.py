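"""Synthetic cohort generator for the amylase-adiposity analysis.

Generates per-individual tables with the statistical structure the downstream
stages assume, under switchable causal scenarios, so the whole pipeline is
testable without access to individual-level cohort data. The generative model
is a recursive structural equation system:

* ``AMY1A``/``AMY2A`` diploid copy numbers are multi-allelic integers in
  [1, 20]; a per-individual parity latent variable (shared between the two
  genes with a configurable coupling probability) reproduces the even-copy
  excess and the cross-gene parity concordance seen in ddPCR data.
* 83 biallelic instrument SNPs in Hardy-Weinberg proportions carry additive
  per-allele effects on BMI, emulating an external BMI GWAS panel.
* BMI = baseline + SNP effects + confounder + (scenario) AMY1 effect + noise.
* Activities = copy-number-driven mean + (scenario) BMI effect + noise, with
  the noise SD found by bisection so that the realized squared Spearman
  correlation between copy number and activity hits the configured target
  (0.34 for AMY1, 0.12 for AMY2 by default).
* 36 metabolites are linearly driven by log-BMI (lactate additionally by AMY1
  activity) and then left-censored: the lowest values become missing at the
  configured rate, which is what minimum-value imputation assumes.

Identical ``(config, seed)`` reproduce byte-identical tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .metabolites import METABOLITES

__all__ = [
    "SimulationConfig",
    "METABOLITE_COLUMNS",
    "generate_snp_truth",
    "generate_cohort",
    "generate_droplet_wells",
    "generate_case_control",
]

_SCENARIOS = ("bmi_to_amy", "amy_to_bmi", "bidirectional", "null")

# Structural constants of the generator (units in comments); see docs/methods.md
# for the calibration rationale.
_AGE_MEAN, _AGE_SD = 47.0, 10.0  # years
_BMI_MEAN = 25.2  # kg/m^2
_BMI_VAR_TARGET = 16.0  # kg^2/m^4 -> SD 4
_AMY1_INTERCEPT, _AMY1_SLOPE = -4.0, 7.0  # IU/L, IU/L per copy
_AMY2_INTERCEPT, _AMY2_SLOPE = 20.0, 5.0
_AMY1_BASE_NOISE_SD = 8.0  # IU/L, copy-number-stage noise
_AMY2_BASE_NOISE_SD = 6.0
_ACTIVITY_FLOOR = 0.1  # IU/L, assay floor
_CONFOUNDER_SD = 1.0  # kg/m^2 contribution of the unmeasured BMI confounder
_FOLLOWUP_DRIFT = 0.02  # log-BMI drift over 9 years
_FOLLOWUP_LOGBMI_SD = 0.08
_FOLLOWUP_ACTIVITY_SD = (8.0, 6.0)  # IU/L (AMY1, AMY2)

#: Metabolites whose association with BMI is negative in the generator.
_NEGATIVE_BMI_METABOLITES = frozenset(
    {
        "1,5-anhydroglucitol",
        "1-oleoylglycerophosphocholine (18:1)",
        "2-linoleoylglycerophosphocholine",
        "asparagine",
        "glycine",
        "histidine",
        "N-acetylglycine",
        "palmitoyl sphingomyelin",
    }
)
_METABOLITE_BMI_GAMMA = 0.35  # panel units per SD of log-BMI


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


#: Cohort-table column name for each panel metabolite, in panel order.
METABOLITE_COLUMNS = tuple(f"met_{_slug(m)}" for m in METABOLITES)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_individuals: int
    n_snps: int = 83
    causal_scenario: str = "bidirectional"
    beta_bmi_on_amy1: float = -4.15  # IU/L per kg/m^2
    beta_bmi_on_amy2: float = -2.53  # IU/L per kg/m^2
    beta_amy1_on_bmi: float = -0.05  # kg/m^2 per IU/L
    cn_mean: float = 7.0  # AMY1A copies
    cn_sd: float = 2.6
    cn2_mean: float = 2.5  # AMY2A copies
    cn2_sd: float = 1.3
    parity_even_fraction: float = 0.6
    parity_coupling: float = 0.95
    target_rho2_amy1: float = 0.34
    target_rho2_amy2: float = 0.12
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate_metabolites: float = 0.03
    followup_fraction: float = 0.75
    beta_amy1_on_bmi_change: float = -0.006  # log-BMI per IU/L over follow-up
    beta_bmi_on_amy1_change: float = -0.20  # IU/L per kg/m^2 over follow-up
    beta_bmi_on_amy2_change: float = -0.18
    beta_amy1_on_lactate: float = 0.012  # panel units per IU/L
    activity_snp_index: int | None = None
    activity_snp_beta: float = 0.0  # IU/L per allele, direct effect on activity
    activity_snp_target: str = "amy1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.causal_scenario not in _SCENARIOS:
            raise ValueError(
                f"unknown causal scenario {self.causal_scenario!r}; "
                f"choose one of {_SCENARIOS}"
            )
        for name in (
            "parity_even_fraction",
            "parity_coupling",
            "target_rho2_amy1",
            "target_rho2_amy2",
            "followup_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.missing_rate_metabolites <= 0.05:
            raise ValueError("missing_rate_metabolites must be in [0, 0.05]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.activity_snp_target not in ("amy1", "amy2"):
            raise ValueError("activity_snp_target must be 'amy1' or 'amy2'")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_snp_truth(config: SimulationConfig) -> pd.DataFrame:
    """Per-SNP ground truth: alleles, MAF and the additive BMI effect.

    Effect alleles are oriented to the BMI-increasing direction (all betas
    positive, uniform in 0.05-0.25 kg/m^2 per allele, a typical GWAS effect
    scale). When a direct activity SNP is configured, its BMI effect is zeroed
    so it acts on BMI only through the activity path and remains a valid
    reverse-direction instrument.
    """
    rng = _rng(config.seed, 1)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, config.n_snps)
    beta = rng.uniform(0.05, 0.25, config.n_snps)
    # draw unambiguous allele pairs so harmonization is strand-safe by default
    pairs = np.array([("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    idx = rng.integers(0, len(pairs), config.n_snps)
    if config.activity_snp_index is not None and config.activity_snp_beta != 0.0:
        beta[config.activity_snp_index] = 0.0
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{i + 1:03d}" for i in range(config.n_snps)],
            "effect_allele": pairs[idx, 0],
            "other_allele": pairs[idx, 1],
            "maf": maf,
            "beta_bmi": beta,
        }
    )


def _draw_parity_coupled(
    rng: np.random.Generator, n: int, even_fraction: float, coupling: float
) -> tuple[np.ndarray, np.ndarray]:
    parity1_even = rng.random(n) < even_fraction
    same = rng.random(n) < coupling
    parity2_even = np.where(same, parity1_even, ~parity1_even)
    return parity1_even, parity2_even


def _draw_copy_number(
    rng: np.random.Generator,
    parity_even: np.ndarray,
    mean: float,
    sd: float,
) -> np.ndarray:
    """Integer copies on [1, 20] with prescribed parity, mean and SD.

    A latent normal draw is rounded to the nearest integer of the required
    parity; the latent SD is deflated by the parity-grid rounding variance
    (grid spacing 2 -> variance 1/3) so the realized SD matches the target.
    """
    latent_sd = np.sqrt(max(sd**2 - 1.0 / 3.0, 0.01))
    x = rng.normal(mean, latent_sd, parity_even.size)
    cn_even = 2.0 * np.round(x / 2.0)
    cn_odd = 2.0 * np.round((x - 1.0) / 2.0) + 1.0
    cn = np.where(parity_even, cn_even, cn_odd)
    cn = np.where(parity_even, np.clip(cn, 2, 20), np.clip(cn, 1, 19))
    return cn.astype(int)


def _calibrate_activity_noise(
    cn: np.ndarray,
    partial: np.ndarray,
    target_rho2: float,
    z: np.ndarray,
    floor: float = _ACTIVITY_FLOOR,
) -> float:
    """Bisect the extra noise SD so rho^2(cn, activity) hits the target.

    ``partial`` is the activity before the calibrated noise; ``z`` is a fixed
    standard-normal draw reused across candidate SDs so the search objective is
    deterministic and monotone in the SD.
    """

    def realized(sd: float) -> float:
        r = stats.spearmanr(cn, np.maximum(partial + sd * z, floor)).statistic
        return float(r * r)

    if realized(0.0) <= target_rho2:
        warnings.warn(
            "activity correlation target unreachable: systematic components "
            "already exceed the allowed non-copy-number variance; "
            "no extra noise added",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    lo, hi = 0.0, max(float(np.std(partial)), 1.0)
    while realized(hi) > target_rho2:
        hi *= 2.0
        if hi > 1e5:  # pragma: no cover - defensive
            break
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if realized(mid) > target_rho2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the per-individual cohort table.

    Columns: identifiers, demographics and covariates, copy numbers,
    activities (with ``total_amylase = amy1_activity + amy2_activity`` exact),
    genotype dosages ``snp_*`` in {0, 1, 2}, medication/disease flags, optional
    9-year follow-up values, and the 36-metabolite panel ``met_*`` with
    left-censored missingness.
    """
    n = config.n_individuals
    truth = generate_snp_truth(config)

    sc = config.causal_scenario
    b2a1 = config.beta_bmi_on_amy1 if sc in ("bmi_to_amy", "bidirectional") else 0.0
    b2a2 = config.beta_bmi_on_amy2 if sc in ("bmi_to_amy", "bidirectional") else 0.0
    a2b = config.beta_amy1_on_bmi if sc in ("amy_to_bmi", "bidirectional") else 0.0

    rng_cov = _rng(config.seed, 2)
    age = rng_cov.normal(_AGE_MEAN, _AGE_SD, n).clip(30, 65)
    sex = rng_cov.integers(0, 2, n)
    alcohol = rng_cov.exponential(8.0, n).clip(0, 120)
    smoking = rng_cov.choice([0, 1, 2], size=n, p=[0.5, 0.3, 0.2])
    pc1 = rng_cov.normal(0.0, 1.0, n)
    pc2 = rng_cov.normal(0.0, 1.0, n)
    diabetic = (rng_cov.random(n) < 0.08).astype(int)
    lipid_drug = (rng_cov.random(n) < 0.10).astype(int)
    htn_drug = (rng_cov.random(n) < 0.15).astype(int)

    rng_geno = _rng(config.seed, 3)
    G = rng_geno.binomial(2, truth["maf"].to_numpy()[None, :], size=(n, config.n_snps))

    rng_cn = _rng(config.seed, 4)
    parity1, parity2 = _draw_parity_coupled(
        rng_cn, n, config.parity_even_fraction, config.parity_coupling
    )
    cn1 = _draw_copy_number(rng_cn, parity1, config.cn_mean, config.cn_sd)
    cn2 = _draw_copy_number(rng_cn, parity2, config.cn2_mean, config.cn2_sd)

    rng_act = _rng(config.seed, 5)
    base1 = (
        _AMY1_INTERCEPT
        + _AMY1_SLOPE * cn1
        + rng_act.normal(0.0, _AMY1_BASE_NOISE_SD, n)
    )
    base2 = (
        _AMY2_INTERCEPT
        + _AMY2_SLOPE * cn2
        + rng_act.normal(0.0, _AMY2_BASE_NOISE_SD, n)
    )
    if config.activity_snp_index is not None and config.activity_snp_beta != 0.0:
        snp_effect = config.activity_snp_beta * G[:, config.activity_snp_index]
        if config.activity_snp_target == "amy1":
            base1 = base1 + snp_effect
        else:
            base2 = base2 + snp_effect

    rng_bmi = _rng(config.seed, 6)
    beta_raw = truth["beta_bmi"].to_numpy()
    maf = truth["maf"].to_numpy()
    grs_component = (G - 2.0 * maf[None, :]) @ beta_raw  # centered genetic effect
    confounder = rng_bmi.normal(0.0, _CONFOUNDER_SD, n)
    systematic = (
        0.03 * (age - _AGE_MEAN)
        + 0.8 * (sex - 0.5)
        + grs_component
        + confounder
        + a2b * (base1 - float(np.mean(base1)))
    )
    eps_sd = np.sqrt(max(_BMI_VAR_TARGET - float(np.var(systematic)), 2.0))
    bmi = (_BMI_MEAN + systematic + rng_bmi.normal(0.0, eps_sd, n)).clip(15.0, 60.0)

    rng_noise = _rng(config.seed, 7)
    z1 = rng_noise.standard_normal(n)
    z2 = rng_noise.standard_normal(n)
    partial1 = base1 + b2a1 * (bmi - _BMI_MEAN)
    partial2 = base2 + b2a2 * (bmi - _BMI_MEAN)
    sd1 = _calibrate_activity_noise(cn1, partial1, config.target_rho2_amy1, z1)
    sd2 = _calibrate_activity_noise(cn2, partial2, config.target_rho2_amy2, z2)
    amy1 = np.maximum(partial1 + sd1 * z1, _ACTIVITY_FLOOR)
    amy2 = np.maximum(partial2 + sd2 * z2, _ACTIVITY_FLOOR)

    rng_fu = _rng(config.seed, 8)
    has_fu = rng_fu.random(n) < config.followup_fraction
    fu_logbmi = (
        np.log(bmi)
        + _FOLLOWUP_DRIFT
        + config.beta_amy1_on_bmi_change * (amy1 - float(np.mean(amy1)))
        + rng_fu.normal(0.0, _FOLLOWUP_LOGBMI_SD, n)
    )
    fu_bmi = np.where(has_fu, np.exp(fu_logbmi), np.nan)
    fu_amy1 = np.maximum(
        amy1
        + config.beta_bmi_on_amy1_change * (bmi - _BMI_MEAN)
        + rng_fu.normal(0.0, _FOLLOWUP_ACTIVITY_SD[0], n),
        _ACTIVITY_FLOOR,
    )
    fu_amy2 = np.maximum(
        amy2
        + config.beta_bmi_on_amy2_change * (bmi - _BMI_MEAN)
        + rng_fu.normal(0.0, _FOLLOWUP_ACTIVITY_SD[1], n),
        _ACTIVITY_FLOOR,
    )
    fu_amy1 = np.where(has_fu, fu_amy1, np.nan)
    fu_amy2 = np.where(has_fu, fu_amy2, np.nan)

    rng_met = _rng(config.seed, 9)
    z_logbmi = (np.log(bmi) - float(np.mean(np.log(bmi)))) / float(np.std(np.log(bmi)))
    panel = {}
    for name, col in zip(METABOLITES, METABOLITE_COLUMNS):
        gamma = _METABOLITE_BMI_GAMMA * (-1.0 if name in _NEGATIVE_BMI_METABOLITES else 1.0)
        vals = 5.0 + gamma * z_logbmi + rng_met.normal(0.0, 1.0, n)
        if name == "lactate":
            vals = vals + config.beta_amy1_on_lactate * (amy1 - float(np.mean(amy1)))
        if config.missing_rate_metabolites > 0:
            cutoff = np.quantile(vals, config.missing_rate_metabolites)
            vals = np.where(vals < cutoff, np.nan, vals)
        panel[col] = vals

    cohort = pd.DataFrame(
        {
            "id": [f"ind_{i + 1:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "amy1_activity": amy1,
            "amy2_activity": amy2,
            "total_amylase": amy1 + amy2,
            "cn_amy1a": cn1,
            "cn_amy2a": cn2,
            "alcohol": alcohol,
            "smoking": smoking,
            "pc1": pc1,
            "pc2": pc2,
            "diabetic_flag": diabetic,
            "lipid_drug_flag": lipid_drug,
            "htn_drug_flag": htn_drug,
            "obesity_case": (bmi >= 30.0).astype(int),
            "followup_bmi": fu_bmi,
            "followup_amy1": fu_amy1,
            "followup_amy2": fu_amy2,
        }
    )
    geno = pd.DataFrame(G, columns=truth["snp_id"].tolist())
    return pd.concat([cohort, geno, pd.DataFrame(panel)], axis=1)


def generate_droplet_wells(
    cohort: pd.DataFrame,
    droplets_per_well: int = 20000,
    ref_lambda: float = 0.5,
    seed: int = 0,
    gene: str = "cn_amy1a",
) -> pd.DataFrame:
    """Simulate one ddPCR well per individual for one target gene.

    The target channel's mean occupancy is ``ref_lambda * CN / 2`` (the
    reference assay sits at two copies per genome); positive-droplet counts are
    binomial with success probability ``1 - exp(-lambda)`` per channel.
    """
    if droplets_per_well <= 0:
        raise ValueError("droplets_per_well must be > 0")
    if ref_lambda <= 0:
        raise ValueError("ref_lambda must be > 0")
    if gene not in cohort.columns:
        raise KeyError(f"cohort lacks copy-number column {gene!r}")
    rng = np.random.default_rng([int(seed), 10])
    cn = cohort[gene].to_numpy(dtype=float)
    lam_t = ref_lambda * cn / 2.0
    p_t = 1.0 - np.exp(-lam_t)
    p_r = 1.0 - np.exp(-ref_lambda)
    return pd.DataFrame(
        {
            "sample_id": cohort["id"].to_numpy(),
            "n_droplets": droplets_per_well,
            "n_target_positive": rng.binomial(droplets_per_well, p_t),
            "n_ref_positive": rng.binomial(droplets_per_well, p_r, size=len(cohort)),
        }
    )


def generate_case_control(
    n_cases: int,
    n_controls: int,
    or_per_copy: float = 0.94,
    seed: int = 0,
    cn_mean: float = 7.2,
    cn_sd: float = 2.6,
    parity_even_fraction: float = 0.6,
    parity_coupling: float = 0.95,
) -> pd.DataFrame:
    """Case-control study with a configurable per-copy obesity odds ratio.

    Case status follows a logistic model in copy number, age and sex; sampling
    continues until both quotas are filled. Columns: ``id, age, sex, cn_amy1a,
    cn_amy2a, obesity_case``.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    if or_per_copy <= 0:
        raise ValueError("or_per_copy must be > 0")
    rng = np.random.default_rng([int(seed), 11])
    log_or = np.log(or_per_copy)
    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    got_cases = got_controls = 0
    while got_cases < n_cases or got_controls < n_controls:
        m = 2 * (n_cases + n_controls)
        age = rng.normal(45.0, 12.0, m).clip(8, 80)
        sex = rng.integers(0, 2, m)
        p1, p2 = _draw_parity_coupled(rng, m, parity_even_fraction, parity_coupling)
        cn1 = _draw_copy_number(rng, p1, cn_mean, cn_sd)
        cn2 = _draw_copy_number(rng, p2, 2.5, 1.3)
        eta = (
            logit(0.4)
            + log_or * (cn1 - cn_mean)
            + 0.02 * (age - 45.0)
            + 0.10 * (sex - 0.5)
        )
        case = rng.random(m) < expit(eta)
        chunk = pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "cn_amy1a": cn1,
                "cn_amy2a": cn2,
                "obesity_case": case.astype(int),
            }
        )
        cases.append(chunk[chunk["obesity_case"] == 1])
        controls.append(chunk[chunk["obesity_case"] == 0])
        got_cases = sum(len(c) for c in cases)
        got_controls = sum(len(c) for c in controls)
    out = pd.concat(
        [pd.concat(cases).head(n_cases), pd.concat(controls).head(n_controls)],
        ignore_index=True,
    )
    out.insert(0, "id", [f"cc_{i + 1:06d}" for i in range(len(out))])
    return out
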