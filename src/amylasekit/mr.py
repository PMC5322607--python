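"""Bidirectional Mendelian randomization between BMI and amylase activity.

Implements the estimator family used for the causal analysis:

* per-SNP Wald ratios (variant->outcome effect over variant->exposure effect),
  with the first-order standard error that treats the denominator as fixed;
* inverse-variance-weighted (IVW) pooling of the per-SNP ratios;
* two-stage least squares (TSLS) with an unweighted genetic risk score (GRS)
  as the instrument;
* MR-Egger weighted regression, whose intercept tests directional pleiotropy;
* the instrument-discovery scan (per-SNP activity association with Bonferroni
  control over the number of tested variants) and the residual-association
  validity check (a candidate instrument must show no association with the
  outcome once the exposure is adjusted for).

Summary statistics are harmonized on allele labels before ratios are formed:
if the two sources report opposite effect alleles for a SNP the outcome effect
sign is flipped. Strand-ambiguous (A/T, C/G) variants are aligned by allele
name only and trigger a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._design import build_design, check_full_rank, residualize
from .meta import FixedEffectMeta

__all__ = [
    "SnpSummaryStat",
    "InstrumentSet",
    "CausalEstimate",
    "HarmonizationError",
    "WeakInstrumentWarning",
    "harmonize",
    "wald_ratio",
    "ivw_pool",
    "build_grs",
    "TwoStageLeastSquares",
    "tsls",
    "EggerRegression",
    "egger_test",
    "snp_scan",
    "instrument_scan",
    "residual_association_check",
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class HarmonizationError(ValueError):
    """Allele labels of two summary statistics cannot be reconciled."""


class WeakInstrumentWarning(UserWarning):
    """First-stage F statistic below the conventional threshold of 10."""


@dataclass
class SnpSummaryStat:
    """Per-SNP effect of one trait, GWAS-summary-statistics style."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float | None = None
    maf: float | None = None
    n: int | None = None
    trait: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5]")


@dataclass
class InstrumentSet:
    """Retained instruments plus the audit trail of exclusions.

    ``grs_weights`` maps each retained SNP to +1/-1: the sign that orients its
    stored effect allele to the exposure-increasing direction.
    """

    snp_ids: list[str]
    grs_weights: dict[str, int]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        excluded = {s for s, _ in self.exclusion_log}
        overlap = excluded & set(self.snp_ids)
        if overlap:
            raise ValueError(f"excluded SNPs present in instrument list: {sorted(overlap)}")
        valid = {"pleiotropic", "failed_qc", "proxy_substituted", "residual_association"}
        for snp, reason in self.exclusion_log:
            base = reason.split(":", 1)[0]
            if base not in valid:
                raise ValueError(f"unknown exclusion reason {reason!r} for {snp}")
        missing_w = set(self.snp_ids) - set(self.grs_weights)
        if missing_w:
            raise ValueError(f"missing GRS weights for {sorted(missing_w)}")


@dataclass
class CausalEstimate:
    """A directed causal effect (exposure -> outcome)."""

    exposure: str
    outcome: str
    beta_causal: float
    se: float
    p: float
    method: str
    instrument: str
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.se >= 0:
            raise ValueError("se must be non-negative")


def harmonize(
    snp_on_outcome: SnpSummaryStat, snp_on_exposure: SnpSummaryStat
) -> SnpSummaryStat:
    """Return the outcome statistic re-oriented to the exposure's effect allele."""
    if snp_on_outcome.snp_id != snp_on_exposure.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {snp_on_outcome.snp_id} vs {snp_on_exposure.snp_id}"
        )
    o, e = snp_on_outcome, snp_on_exposure
    if frozenset((e.effect_allele, e.other_allele)) in _AMBIGUOUS_PAIRS:
        warnings.warn(
            f"{e.snp_id}: strand-ambiguous alleles "
            f"({e.effect_allele}/{e.other_allele}); aligned by allele name only",
            UserWarning,
            stacklevel=2,
        )
    if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
        return o
    if (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
        flipped = SnpSummaryStat(
            snp_id=o.snp_id,
            effect_allele=e.effect_allele,
            other_allele=e.other_allele,
            beta=-o.beta,
            se=o.se,
            p=o.p,
            maf=o.maf,
            n=o.n,
            trait=o.trait,
        )
        return flipped
    raise HarmonizationError(
        f"{o.snp_id}: alleles {o.effect_allele}/{o.other_allele} cannot be "
        f"reconciled with {e.effect_allele}/{e.other_allele}"
    )


def wald_ratio(
    snp_on_outcome: SnpSummaryStat,
    snp_on_exposure: SnpSummaryStat,
    second_order_se: bool = False,
) -> CausalEstimate:
    """Per-SNP causal ratio beta_outcome / beta_exposure.

    The default standard error is first-order, ``se_outcome / |beta_exposure|``,
    treating the exposure effect as fixed. ``second_order_se=True`` adds the
    exposure-side sampling term of the delta method.
    """
    out = harmonize(snp_on_outcome, snp_on_exposure)
    exp = snp_on_exposure
    if exp.beta == 0:
        raise ZeroDivisionError(f"{exp.snp_id}: zero exposure effect, ratio undefined")
    ratio = out.beta / exp.beta
    se = out.se / abs(exp.beta)
    if second_order_se:
        se = math.sqrt(
            out.se**2 / exp.beta**2 + out.beta**2 * exp.se**2 / exp.beta**4
        )
    z = ratio / se
    return CausalEstimate(
        exposure=exp.trait or "exposure",
        outcome=out.trait or "outcome",
        beta_causal=float(ratio),
        se=float(se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        method="ivw_ratio",
        instrument=exp.snp_id,
        n=out.n,
    )


def ivw_pool(estimates: Sequence[CausalEstimate]) -> CausalEstimate:
    """Inverse-variance-weighted pooling of per-SNP causal ratios."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("at least one estimate is required")
    pairs = {(e.exposure, e.outcome) for e in estimates}
    if len(pairs) > 1:
        raise ValueError(f"mixed exposure/outcome pairs: {sorted(pairs)}")
    fe = FixedEffectMeta().fit([e.beta_causal for e in estimates], [e.se for e in estimates])
    exposure, outcome = next(iter(pairs))
    return CausalEstimate(
        exposure=exposure,
        outcome=outcome,
        beta_causal=fe.beta_,
        se=fe.se_,
        p=fe.p_,
        method="ivw_ratio",
        instrument=f"IVW over {fe.k_} SNPs",
        n=estimates[0].n,
    )


def build_grs(genotypes: pd.DataFrame, instruments: InstrumentSet) -> pd.Series:
    """Unweighted allele-count genetic risk score.

    Each SNP's dosage is oriented to its exposure-increasing allele using the
    +1/-1 weights of the instrument set (a -1 weight counts ``2 - dosage``),
    then dosages are summed. The score therefore lies in ``[0, 2 * n_snps]``.
    """
    missing = [s for s in instruments.snp_ids if s not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype matrix lacks instrument SNPs: {missing}")
    G = genotypes[instruments.snp_ids].astype(float)
    if ((G < 0) | (G > 2)).any().any():
        raise ValueError("dosages must lie in [0, 2]")
    signs = np.array([instruments.grs_weights[s] for s in instruments.snp_ids])
    oriented = np.where(signs > 0, G.to_numpy(), 2.0 - G.to_numpy())
    return pd.Series(oriented.sum(axis=1), index=genotypes.index, name="grs")


class TwoStageLeastSquares(BaseEstimator):
    """TSLS causal-effect estimator with a single instrument column.

    Stage 1 regresses the exposure on the instrument plus covariates; stage 2
    regresses the outcome on the fitted exposure plus covariates. The reported
    standard error is the standard IV sandwich-free formula: stage-2
    coefficient covariance uses residuals computed against the *observed*
    exposure, not the fitted one.

    Attributes
    ----------
    beta_causal_, se_, p_ : float
        Causal coefficient of the exposure, its SE, and the two-sided normal P.
    first_stage_f_ : float
        F statistic of the instrument in the first stage; a value below 10
        raises :class:`WeakInstrumentWarning`.
    n_ : int
        Complete-case sample size.
    """

    def __init__(
        self,
        exposure: str = "bmi",
        outcome: str = "amy1_activity",
        instrument: str = "grs",
        covariates: Sequence[str] = ("age", "sex", "pc1", "pc2"),
    ):
        self.exposure = exposure
        self.outcome = outcome
        self.instrument = instrument
        self.covariates = covariates

    def fit(self, cohort: pd.DataFrame, y=None):
        used = [self.outcome, self.exposure, self.instrument, *self.covariates]
        data = cohort[used].dropna()
        n = len(data)
        yv = data[self.outcome].astype(float).to_numpy()
        x = data[self.exposure].astype(float).to_numpy()

        Z = build_design(data, [self.instrument, *self.covariates])  # instruments
        X = build_design(data, [self.exposure, *self.covariates])  # regressors
        check_full_rank(Z)
        check_full_rank(X)

        # first-stage F for the excluded instrument
        fs = sm.OLS(x, Z).fit()
        tval = fs.params[self.instrument] / fs.bse[self.instrument]
        self.first_stage_f_ = float(tval**2)
        if self.first_stage_f_ < 10:
            warnings.warn(
                f"weak instrument: first-stage F = {self.first_stage_f_:.2f}",
                WeakInstrumentWarning,
                stacklevel=2,
            )

        Zm = Z.to_numpy(dtype=float)
        Xm = X.to_numpy(dtype=float)
        # project regressors on the instrument space
        Q, _ = np.linalg.qr(Zm)
        Xhat = Q @ (Q.T @ Xm)
        XtX = Xhat.T @ Xhat
        beta = np.linalg.solve(XtX, Xhat.T @ yv)
        resid = yv - Xm @ beta  # residuals against observed regressors
        dof = n - Xm.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(XtX)
        j = list(X.columns).index(self.exposure)
        self.beta_causal_ = float(beta[j])
        self.se_ = float(math.sqrt(cov[j, j]))
        z = self.beta_causal_ / self.se_
        self.p_ = float(2.0 * stats.norm.sf(abs(z)))
        self.n_ = int(n)
        return self

    def estimate_(self) -> CausalEstimate:
        return CausalEstimate(
            exposure=self.exposure,
            outcome=self.outcome,
            beta_causal=self.beta_causal_,
            se=self.se_,
            p=self.p_,
            method="tsls",
            instrument=self.instrument,
            n=self.n_,
        )


def tsls(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    instrument: str,
    covariates: Sequence[str] = ("age", "sex", "pc1", "pc2"),
) -> CausalEstimate:
    """Functional wrapper over :class:`TwoStageLeastSquares`."""
    est = TwoStageLeastSquares(
        exposure=exposure, outcome=outcome, instrument=instrument, covariates=tuple(covariates)
    ).fit(cohort)
    return est.estimate_()


class EggerRegression(BaseEstimator):
    """MR-Egger weighted regression of outcome effects on exposure effects.

    Weights are ``1 / se_outcome**2`` and the intercept is free; exposure
    effects are oriented positive (flipping the matching outcome effect) before
    fitting so the intercept has a consistent sign interpretation. A non-zero
    intercept indicates directional pleiotropy.

    Attributes: ``intercept_``, ``intercept_se_``, ``intercept_p_`` and the
    corresponding ``slope_*`` triple (t-distributed P values, k - 2 df).
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, beta_exposure, beta_outcome, se_outcome):
        bx = np.asarray(beta_exposure, dtype=float)
        by = np.asarray(beta_outcome, dtype=float)
        so = np.asarray(se_outcome, dtype=float)
        if bx.shape != by.shape or bx.shape != so.shape or bx.ndim != 1:
            raise ValueError("inputs must be 1-d arrays of equal length")
        if bx.size < 3:
            raise ValueError("Egger regression needs at least 3 instruments")
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        X = bx[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones_like(bx), bx])
        fit = sm.WLS(by, X, weights=1.0 / so**2).fit()
        if self.fit_intercept:
            self.intercept_ = float(fit.params[0])
            self.intercept_se_ = float(fit.bse[0])
            self.intercept_p_ = float(fit.pvalues[0])
            j = 1
        else:
            self.intercept_ = 0.0
            self.intercept_se_ = float("nan")
            self.intercept_p_ = float("nan")
            j = 0
        self.slope_ = float(fit.params[j])
        self.slope_se_ = float(fit.bse[j])
        self.slope_p_ = float(fit.pvalues[j])
        self.k_ = int(bx.size)
        return self


def egger_test(
    snp_on_exposure, snp_on_outcome, se_outcome
) -> tuple[float, float, float]:
    """Egger pleiotropy test: returns (intercept, se, two-sided P)."""
    est = EggerRegression().fit(snp_on_exposure, snp_on_outcome, se_outcome)
    return est.intercept_, est.intercept_se_, est.intercept_p_


def snp_scan(
    cohort: pd.DataFrame,
    phenotype: str,
    snp_columns: Sequence[str],
    covariates: Sequence[str] = ("age", "sex", "bmi", "pc1", "pc2"),
) -> pd.DataFrame:
    """Per-SNP adjusted linear association of a phenotype with each dosage.

    All SNPs share the covariate design, so the scan runs as one residualized
    (Frisch-Waugh-Lovell) pass; coefficients and t-based P values are identical
    to fitting each full OLS model separately.
    """
    used = [phenotype, *covariates, *snp_columns]
    data = cohort[used].dropna()
    n = len(data)
    C = build_design(data, list(covariates)).to_numpy(dtype=float)
    yv = data[phenotype].astype(float).to_numpy()
    G = data[list(snp_columns)].to_numpy(dtype=float)

    ry = residualize(yv, C)
    RG = residualize(G, C)
    gss = np.einsum("ij,ij->j", RG, RG)
    ok = gss > 1e-12  # monomorphic SNPs cannot be tested
    beta = np.full(len(snp_columns), np.nan)
    se = np.full(len(snp_columns), np.nan)
    beta[ok] = (RG[:, ok] * ry[:, None]).sum(axis=0) / gss[ok]
    dof = n - C.shape[1] - 1
    sse = (ry @ ry) - beta[ok] ** 2 * gss[ok]
    se[ok] = np.sqrt(np.maximum(sse, 0.0) / dof / gss[ok])
    with np.errstate(invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame(
        {"snp_id": list(snp_columns), "beta": beta, "se": se, "p": p, "n": n}
    )


def instrument_scan(
    cohort: pd.DataFrame,
    activity: str,
    n_tests: int | None = None,
    snp_columns: Sequence[str] | None = None,
    covariates: Sequence[str] = ("age", "sex", "bmi", "pc1", "pc2"),
) -> tuple[pd.DataFrame, float]:
    """Scan SNPs for association with an amylase activity; Bonferroni-retain.

    ``n_tests`` defaults to the number of scanned SNPs but can be set to the
    full array size (e.g. 124571 tested variants) so the threshold matches a
    genome-scale scan. Returns the retained rows and the threshold
    ``0.05 / n_tests``.
    """
    if snp_columns is None:
        snp_columns = [c for c in cohort.columns if c.startswith("snp_")]
    if n_tests is None:
        n_tests = len(snp_columns)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = 0.05 / n_tests
    res = snp_scan(cohort, activity, snp_columns, covariates=covariates)
    kept = res[res["p"] < threshold].reset_index(drop=True)
    return kept, threshold


def residual_association_check(
    cohort: pd.DataFrame,
    candidate: str,
    outcome: str,
    adjust_for: str,
    covariates: Sequence[str] = ("age", "sex", "pc1", "pc2"),
) -> float:
    """P value of a candidate instrument's residual association with the outcome.

    Regresses ``outcome`` on ``candidate + adjust_for + covariates`` and
    returns the candidate's two-sided P. A small P (<= 0.05) disqualifies the
    candidate as an instrument: it reaches the outcome through a path not fully
    mediated by the exposure.
    """
    used = [outcome, candidate, adjust_for, *covariates]
    data = cohort[used].dropna()
    X = build_design(data, [candidate, adjust_for, *covariates])
    try:
        check_full_rank(X)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"candidate {candidate!r} is collinear with {adjust_for!r}"
        ) from exc
    fit = sm.OLS(data[outcome].astype(float).to_numpy(), X).fit()
    return float(fit.pvalues[candidate])
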