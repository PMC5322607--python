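import numpy as np
import pytest

from amylasekit.mr import (
    InstrumentSet,
    SnpSummaryStat,
    build_grs,
    ivw_pool,
    snp_scan,
    tsls,
    wald_ratio,
)
from amylasekit.simulate import SimulationConfig, generate_cohort, generate_snp_truth


@pytest.fixture(scope="session")
def cohort_factory():
    """Factory for synthetic cohorts: ``cohort_factory(seed=..., **config_kw)``."""

    def make(n_individuals=3000, seed=11, **kw):
        cfg = SimulationConfig(n_individuals=n_individuals, seed=seed, **kw)
        return generate_cohort(cfg), generate_snp_truth(cfg)

    return make


@pytest.fixture(scope="session")
def default_cohort(cohort_factory):
    """One mid-sized bidirectional-scenario cohort shared across read-only tests."""
    return cohort_factory(n_individuals=3000, seed=11)


def ivw_from_cohort(cohort, truth, outcome="amy1_activity"):
    """IVW causal estimate of BMI on an activity, using the SNP truth table as
    the external exposure panel and in-sample adjusted outcome regressions."""
    snps = truth["snp_id"].tolist()
    scan = snp_scan(cohort, outcome, snps, covariates=("age", "sex", "pc1", "pc2"))
    ratios = []
    for t, s in zip(truth.itertuples(index=False), scan.itertuples(index=False)):
        if t.beta_bmi == 0 or not np.isfinite(s.beta):
            continue
        exp_stat = SnpSummaryStat(
            t.snp_id, t.effect_allele, t.other_allele, t.beta_bmi, 1e-6, trait="bmi"
        )
        out_stat = SnpSummaryStat(
            t.snp_id, t.effect_allele, t.other_allele, s.beta, s.se, trait=outcome
        )
        ratios.append(wald_ratio(out_stat, exp_stat))
    return ivw_pool(ratios)


def tsls_from_cohort(cohort, truth, exposure="bmi", outcome="amy1_activity"):
    """GRS-instrumented TSLS on a simulated cohort."""
    snps = truth["snp_id"].tolist()
    inst = InstrumentSet(snp_ids=snps, grs_weights={s: 1 for s in snps})
    work = cohort.copy()
    work["grs"] = build_grs(cohort[snps], inst)
    return tsls(work, exposure=exposure, outcome=outcome, instrument="grs")
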