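"""End-to-end orchestration: simulate -> cnv-call -> assoc -> mr -> meta -> metabolites.

Stages hand data to each other through flat files in the output directory, so
any stage can also be re-run standalone on real exports with matching columns.
A manifest records the configuration hash, the seed, per-stage row counts and
every exclusion (QC-failed wells, out-of-range activities, subgroup removals,
incomplete cases) so that input n = analysed n + exclusions for each model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as akio
from .association import (
    TraitAssociation,
    fit_change_model,
    prepare_activities,
)
from .ddpcr import CopyNumberCaller
from .mr import (
    InstrumentSet,
    SnpSummaryStat,
    build_grs,
    egger_test,
    instrument_scan,
    ivw_pool,
    residual_association_check,
    snp_scan,
    tsls,
    wald_ratio,
)
from .meta import StudyEstimate, fixed_effect_meta
from .metabolites import MinimumImputer, metabolite_screen
from .simulate import (
    METABOLITE_COLUMNS,
    SimulationConfig,
    generate_cohort,
    generate_droplet_wells,
    generate_snp_truth,
)

logger = logging.getLogger("amylasekit")

ALL_STAGES = ("simulate", "cnv_call", "assoc", "mr", "meta", "metabolites")


@dataclass
class PipelineConfig:
    """Run-level configuration: stage list plus per-stage parameters."""

    out_dir: str | Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    droplets_per_well: int = 20000
    ref_lambda: float = 0.5
    verbosity: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.simulation is None:
            self.simulation = SimulationConfig(n_individuals=2000, seed=self.seed)


def _config_hash(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    sim = config.simulation
    cohort = generate_cohort(sim)
    truth = generate_snp_truth(sim)
    akio.write_cohort(cohort, out / "cohort.tsv")
    truth.to_csv(out / "snp_truth.tsv", sep="\t", index=False)
    for gene, tag in (("cn_amy1a", "amy1a"), ("cn_amy2a", "amy2a")):
        wells = generate_droplet_wells(
            cohort,
            droplets_per_well=config.droplets_per_well,
            ref_lambda=config.ref_lambda,
            seed=sim.seed,
            gene=gene,
        )
        akio.write_wells(wells, out / f"wells_{tag}.csv")
    manifest["stages"]["simulate"] = {
        "n_individuals": len(cohort),
        "n_snps": sim.n_snps,
        "outputs": ["cohort.tsv", "snp_truth.tsv", "wells_amy1a.csv", "wells_amy2a.csv"],
    }
    logger.info("simulate: %d individuals, %d SNPs", len(cohort), sim.n_snps)


def _stage_cnv_call(config: PipelineConfig, out: Path, manifest: dict) -> None:
    entry = {"genes": {}, "outputs": []}
    for tag in ("amy1a", "amy2a"):
        wells = akio.read_wells(out / f"wells_{tag}.csv")
        caller = CopyNumberCaller(drop_failed=True)
        calls = caller.transform(wells)
        akio.write_cn_calls(calls, out / f"cn_calls_{tag}.tsv")
        entry["genes"][tag] = {
            "n_wells": len(wells),
            "n_qc_failed": caller.n_qc_failed_,
            "n_called": len(calls),
        }
        entry["outputs"].append(f"cn_calls_{tag}.tsv")
        logger.info(
            "cnv_call %s: %d wells, %d QC-failed dropped", tag, len(wells),
            caller.n_qc_failed_,
        )
    manifest["stages"]["cnv_call"] = entry


def _assoc_row(est: TraitAssociation, n_input: int, n_range_excluded: int) -> dict:
    return {
        "trait": est.trait,
        "exposure": est.exposure,
        "n": est.n_,
        "effect": est.effect_,
        "se": est.se_,
        "p": est.p_,
        "n_input": n_input,
        "excluded_out_of_range": n_range_excluded,
        "excluded_subgroup": est.n_excluded_subgroup_,
        "excluded_missing": est.n_excluded_missing_,
    }


def _stage_assoc(config: PipelineConfig, out: Path, manifest: dict) -> None:
    cohort = akio.read_cohort(out / "cohort.tsv")
    n_input = len(cohort)
    _, in_range = prepare_activities(cohort["total_amylase"], cohort["amy2_activity"])
    analysed = cohort[in_range].reset_index(drop=True)
    n_range_excluded = n_input - len(analysed)
    logger.info("assoc: %d of %d within activity normal ranges", len(analysed), n_input)

    covs_no_bmi = ("age", "sex", "alcohol", "smoking", "pc1", "pc2")
    rows = []
    for exposure in ("amy1_activity", "amy2_activity", "cn_amy1a", "cn_amy2a"):
        est = TraitAssociation(
            trait="bmi", exposure=exposure, covariates=covs_no_bmi,
            log_transform_trait=True,
        ).fit(analysed)
        rows.append(_assoc_row(est, n_input, n_range_excluded))

    if analysed["followup_bmi"].notna().any():
        for predictor in ("amy1_activity", "amy2_activity"):
            res = fit_change_model(
                analysed, predictor=predictor, response_change="followup_bmi",
                baseline="bmi", log_transform=True,
            )
            rows.append(
                {
                    "trait": "followup_bmi", "exposure": predictor, "n": res.n,
                    "effect": res.effect, "se": res.se, "p": res.p,
                    "n_input": n_input,
                    "excluded_out_of_range": n_range_excluded,
                    "excluded_subgroup": 0,
                    "excluded_missing": len(analysed) - res.n,
                }
            )
    else:
        logger.info("assoc: follow-up columns empty, change models skipped")
        manifest["stages"].setdefault("notices", []).append("change models skipped")

    res_df = pd.DataFrame(rows)
    res_df.to_csv(out / "assoc_results.tsv", sep="\t", index=False)
    manifest["stages"]["assoc"] = {
        "n_input": n_input,
        "excluded_out_of_range": n_range_excluded,
        "models": res_df[["trait", "exposure", "n", "excluded_missing"]].to_dict("records"),
        "outputs": ["assoc_results.tsv"],
    }


def _stage_mr(config: PipelineConfig, out: Path, manifest: dict) -> None:
    cohort = akio.read_cohort(out / "cohort.tsv")
    truth = pd.read_csv(out / "snp_truth.tsv", sep="\t")
    snps = truth["snp_id"].tolist()
    estimates = []

    # forward direction: per-SNP Wald ratios against the external BMI panel + IVW
    for outcome in ("amy1_activity", "amy2_activity"):
        scan = snp_scan(cohort, outcome, snps, covariates=("age", "sex", "pc1", "pc2"))
        ratios = []
        bx, by, so = [], [], []
        for t, s in zip(truth.itertuples(index=False), scan.itertuples(index=False)):
            if t.beta_bmi == 0 or not np.isfinite(s.beta):
                continue
            exp_stat = SnpSummaryStat(
                snp_id=t.snp_id, effect_allele=t.effect_allele,
                other_allele=t.other_allele, beta=t.beta_bmi, se=1e-6, trait="bmi",
            )
            out_stat = SnpSummaryStat(
                snp_id=t.snp_id, effect_allele=t.effect_allele,
                other_allele=t.other_allele, beta=s.beta, se=s.se, trait=outcome,
                n=int(s.n),
            )
            ratios.append(wald_ratio(out_stat, exp_stat))
            bx.append(t.beta_bmi); by.append(s.beta); so.append(s.se)
        pooled = ivw_pool(ratios)
        intercept, _, p_int = egger_test(np.array(bx), np.array(by), np.array(so))
        estimates.append(
            {
                "exposure": "bmi", "outcome": outcome, "method": "ivw_ratio",
                "beta_causal": pooled.beta_causal, "se": pooled.se, "p": pooled.p,
                "instrument": pooled.instrument, "n": len(cohort),
                "egger_intercept": intercept, "egger_p": p_int,
            }
        )
        # TSLS with the unweighted GRS as instrument
        inst = InstrumentSet(snp_ids=snps, grs_weights={s: 1 for s in snps})
        work = cohort.copy()
        work["grs"] = build_grs(cohort[snps], inst)
        ts = tsls(work, exposure="bmi", outcome=outcome, instrument="grs")
        estimates.append(
            {
                "exposure": "bmi", "outcome": outcome, "method": "tsls",
                "beta_causal": ts.beta_causal, "se": ts.se, "p": ts.p,
                "instrument": "GRS over %d SNPs" % len(snps), "n": ts.n,
                "egger_intercept": np.nan, "egger_p": np.nan,
            }
        )

    # reverse direction: scan for activity instruments, validity-check, TSLS
    for activity, exposure_name in (("amy1_activity", "amy1"), ("amy2_activity", "amy2")):
        kept, threshold = instrument_scan(cohort, activity, snp_columns=snps)
        usable = []
        for row in kept.itertuples(index=False):
            p_res = residual_association_check(
                cohort, candidate=row.snp_id, outcome="bmi", adjust_for=activity
            )
            if p_res > 0.05:
                usable.append(row.snp_id)
            else:
                logger.info(
                    "mr: %s rejected as %s instrument (residual BMI association "
                    "P=%.3g)", row.snp_id, exposure_name, p_res,
                )
        if usable:
            ts = tsls(cohort, exposure=activity, outcome="bmi", instrument=usable[0])
            estimates.append(
                {
                    "exposure": activity, "outcome": "bmi", "method": "tsls",
                    "beta_causal": ts.beta_causal, "se": ts.se, "p": ts.p,
                    "instrument": usable[0], "n": ts.n,
                    "egger_intercept": np.nan, "egger_p": np.nan,
                }
            )
        else:
            logger.info(
                "mr: no valid %s->bmi instrument at threshold %.3g",
                exposure_name, threshold,
            )

    df = pd.DataFrame(estimates)
    df.to_csv(out / "causal_estimates.tsv", sep="\t", index=False)
    manifest["stages"]["mr"] = {
        "n_estimates": len(df), "outputs": ["causal_estimates.tsv"],
    }


def _stage_meta(config: PipelineConfig, out: Path, manifest: dict) -> None:
    """Discovery/replication split of the activity scan, pooled fixed-effect."""
    cohort = akio.read_cohort(out / "cohort.tsv")
    snps = [c for c in cohort.columns if c.startswith("snp_")]
    n_disc = int(0.8 * len(cohort))
    disc, repl = cohort.iloc[:n_disc], cohort.iloc[n_disc:]
    rows = []
    for activity in ("amy1_activity", "amy2_activity"):
        scan_d = snp_scan(disc, activity, snps)
        top = scan_d.loc[scan_d["p"].idxmin()]
        scan_r = snp_scan(repl, activity, [top["snp_id"]])
        pooled = fixed_effect_meta(
            [
                StudyEstimate("discovery", top["beta"], top["se"], int(top["n"])),
                StudyEstimate(
                    "replication", float(scan_r["beta"].iloc[0]),
                    float(scan_r["se"].iloc[0]), int(scan_r["n"].iloc[0]),
                ),
            ]
        )
        rows.append(
            {
                "activity": activity, "snp_id": top["snp_id"],
                "beta_discovery": top["beta"], "se_discovery": top["se"],
                "beta_replication": float(scan_r["beta"].iloc[0]),
                "se_replication": float(scan_r["se"].iloc[0]),
                "beta_meta": pooled.beta_pooled, "se_meta": pooled.se_pooled,
                "p_meta": pooled.p_pooled, "q": pooled.q, "p_het": pooled.p_het,
            }
        )
    pd.DataFrame(rows).to_csv(out / "meta_results.tsv", sep="\t", index=False)
    manifest["stages"]["meta"] = {"n_rows": len(rows), "outputs": ["meta_results.tsv"]}


def _stage_metabolites(config: PipelineConfig, out: Path, manifest: dict) -> None:
    cohort = akio.read_cohort(out / "cohort.tsv")
    panel = cohort[list(METABOLITE_COLUMNS)]
    imputer = MinimumImputer().fit(panel)
    imputed = imputer.transform(panel)
    results = []
    for adjust_bmi in (False, True):
        res = metabolite_screen(cohort, imputed, "amy1_activity", adjust_bmi=adjust_bmi)
        res.insert(1, "bmi_adjusted", adjust_bmi)
        results.append(res)
    res_df = pd.concat(results, ignore_index=True)
    res_df.to_csv(out / "metabolite_results.tsv", sep="\t", index=False)
    manifest["stages"]["metabolites"] = {
        "max_missing_rate": float(imputer.missing_rate_.max()),
        "n_models": len(res_df),
        "outputs": ["metabolite_results.tsv"],
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cnv_call": _stage_cnv_call,
    "assoc": _stage_assoc,
    "mr": _stage_mr,
    "meta": _stage_meta,
    "metabolites": _stage_metabolites,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out, manifest)
        except Exception as exc:
            manifest["failed_stage"] = stage
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
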