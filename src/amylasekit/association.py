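"""Covariate-adjusted association models for metabolic traits.

The workhorse is a linear (or logistic) regression of a trait on an amylase
exposure -- plasma enzymatic activity, gene copy number, or a SNP dosage --
adjusted for age, sex, BMI, daily alcohol intake, smoking status and two
ancestry principal components. Right-skewed traits (BMI, AST, fasting insulin,
triglycerides, HOMA-2B, HOMA-2IR) are natural-log transformed before fitting;
when BMI itself is the trait it is dropped from the covariate set.

Subgroup conventions follow standard epidemiological practice for this design:
glucose traits are analysed in non-diabetic participants only, lipid traits in
participants not on lipid-lowering drugs, and blood pressure in participants
not on anti-hypertensive drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._design import build_design, check_full_rank

__all__ = [
    "DEFAULT_COVARIATES",
    "AMY2_NORMAL_RANGE",
    "TOTAL_NORMAL_RANGE",
    "AssociationSpec",
    "AssociationResult",
    "prepare_activities",
    "TraitAssociation",
    "fit_association",
    "fit_change_model",
    "fit_obesity_logistic",
]

#: Full adjustment set used for trait models (BMI removed when it is the trait).
DEFAULT_COVARIATES = ("age", "sex", "bmi", "alcohol", "smoking", "pc1", "pc2")

#: Normal range of AMY2 plasma enzymatic activity, U/L.
AMY2_NORMAL_RANGE = (13.0, 53.0)
#: Normal range of total amylase plasma enzymatic activity, U/L.
TOTAL_NORMAL_RANGE = (29.0, 99.0)

_SUBGROUPS = {
    "all": None,
    "non_diabetic": ("diabetic_flag", 0),
    "no_lipid_drugs": ("lipid_drug_flag", 0),
    "no_htn_drugs": ("htn_drug_flag", 0),
}


@dataclass
class AssociationSpec:
    """Declarative description of one association model."""

    trait: str
    exposure: str
    covariates: Sequence[str] = DEFAULT_COVARIATES
    log_transform_trait: bool = False
    subgroup_filter: str = "all"
    model: str = "linear"

    def __post_init__(self) -> None:
        if self.trait == self.exposure:
            raise ValueError("trait and exposure must differ")
        if self.exposure in self.covariates:
            raise ValueError(f"exposure {self.exposure!r} cannot also be a covariate")
        if self.subgroup_filter not in _SUBGROUPS:
            raise ValueError(f"unknown subgroup filter {self.subgroup_filter!r}")
        if self.model not in ("linear", "logistic"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class AssociationResult:
    """Exposure coefficient from one fitted association model."""

    trait: str
    exposure: str
    effect: float
    se: float
    p: float
    n: int
    or_: float | None = None
    or_ci: tuple[float, float] | None = field(default=None)


def prepare_activities(
    total_amylase, amy2
) -> tuple[np.ndarray, np.ndarray]:
    """Derive AMY1 activity and the normal-range inclusion flag.

    AMY1 activity is total amylase activity minus AMY2 activity. An individual
    is in range when AMY2 is within 13-53 U/L and total amylase within
    29-99 U/L; out-of-range individuals are excluded from analyses. A negative
    derived AMY1 (AMY2 exceeding total) is flagged out of range as an invalid
    measurement pair.
    """
    total = np.asarray(total_amylase, dtype=float)
    amy2 = np.asarray(amy2, dtype=float)
    if np.any(total < 0) or np.any(amy2 < 0):
        raise ValueError("activities must be non-negative")
    amy1 = total - amy2
    in_range = (
        (amy2 >= AMY2_NORMAL_RANGE[0])
        & (amy2 <= AMY2_NORMAL_RANGE[1])
        & (total >= TOTAL_NORMAL_RANGE[0])
        & (total <= TOTAL_NORMAL_RANGE[1])
        & (amy1 >= 0)
    )
    return amy1, in_range


def _apply_subgroup(df: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    rule = _SUBGROUPS[subgroup]
    if rule is None:
        return df
    col, keep_value = rule
    if col not in df.columns:
        raise KeyError(f"subgroup filter {subgroup!r} needs column {col!r}")
    return df[df[col] == keep_value]


class TraitAssociation(BaseEstimator):
    """Covariate-adjusted association of one trait with one exposure.

    Parameters mirror :class:`AssociationSpec`. ``fit`` takes the cohort table
    (one row per individual) and performs complete-case estimation: rows with a
    missing trait, exposure or covariate are dropped and counted in
    ``n_excluded_missing_``.

    Attributes
    ----------
    effect_, se_, p_ : float
        Exposure coefficient, its standard error, and the two-sided P
        (t-based for linear models, Wald-normal for logistic).
    n_ : int
        Analysed sample size.
    or_, or_ci_ :
        Odds ratio per exposure unit with Wald 95% CI (logistic only).
    """

    def __init__(
        self,
        trait: str = "bmi",
        exposure: str = "amy1_activity",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        log_transform_trait: bool = False,
        subgroup_filter: str = "all",
        model: str = "linear",
    ):
        self.trait = trait
        self.exposure = exposure
        self.covariates = covariates
        self.log_transform_trait = log_transform_trait
        self.subgroup_filter = subgroup_filter
        self.model = model

    def _spec(self) -> AssociationSpec:
        return AssociationSpec(
            trait=self.trait,
            exposure=self.exposure,
            covariates=tuple(self.covariates),
            log_transform_trait=self.log_transform_trait,
            subgroup_filter=self.subgroup_filter,
            model=self.model,
        )

    def fit(self, cohort: pd.DataFrame, y=None):
        spec = self._spec()
        sub = _apply_subgroup(cohort, spec.subgroup_filter)
        self.n_excluded_subgroup_ = len(cohort) - len(sub)

        used = [spec.trait, spec.exposure, *spec.covariates]
        missing_cols = [c for c in used if c not in sub.columns]
        if missing_cols:
            raise KeyError(f"cohort table is missing columns: {missing_cols}")
        data = sub[used].dropna()
        self.n_excluded_missing_ = len(sub) - len(data)

        yv = data[spec.trait].astype(float).to_numpy()
        if spec.log_transform_trait:
            bad = int(np.sum(yv <= 0))
            if bad:
                raise ValueError(
                    f"log transform of {spec.trait!r}: {bad} non-positive values"
                )
            yv = np.log(yv)

        X = build_design(data, [spec.exposure, *spec.covariates])
        if len(data) <= X.shape[1] + 1:
            raise ValueError(
                f"too few complete cases (n={len(data)}) for {X.shape[1]} parameters"
            )
        check_full_rank(X)

        if spec.model == "linear":
            fit = sm.OLS(yv, X).fit()
            p = float(fit.pvalues[spec.exposure])
        else:
            classes = np.unique(yv)
            if classes.size != 2:
                raise ValueError("logistic model needs exactly two outcome classes")
            try:
                fit = sm.Logit(yv, X).fit(disp=0)
            except Exception as exc:  # pragma: no cover - separation is data-dependent
                raise RuntimeError(f"logistic estimation failed: {exc}") from exc
            converged = fit.mle_retvals.get("converged", True)
            if not converged or not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
                raise RuntimeError(
                    "logistic estimation failed (no convergence or separation)"
                )
            beta = float(fit.params[spec.exposure])
            se = float(fit.bse[spec.exposure])
            p = float(2.0 * stats.norm.sf(abs(beta / se)))

        self.effect_ = float(fit.params[spec.exposure])
        self.se_ = float(fit.bse[spec.exposure])
        self.p_ = p
        self.n_ = int(len(data))
        if spec.model == "logistic":
            z = stats.norm.ppf(0.975)
            self.or_ = math.exp(self.effect_)
            self.or_ci_ = (
                math.exp(self.effect_ - z * self.se_),
                math.exp(self.effect_ + z * self.se_),
            )
        else:
            self.or_ = None
            self.or_ci_ = None
        self._fit = fit
        return self

    def result_(self) -> AssociationResult:
        return AssociationResult(
            trait=self.trait,
            exposure=self.exposure,
            effect=self.effect_,
            se=self.se_,
            p=self.p_,
            n=self.n_,
            or_=self.or_,
            or_ci=self.or_ci_,
        )


def fit_association(cohort: pd.DataFrame, spec: AssociationSpec) -> AssociationResult:
    """Fit one association model described by ``spec`` on the cohort table."""
    est = TraitAssociation(
        trait=spec.trait,
        exposure=spec.exposure,
        covariates=tuple(spec.covariates),
        log_transform_trait=spec.log_transform_trait,
        subgroup_filter=spec.subgroup_filter,
        model=spec.model,
    ).fit(cohort)
    return est.result_()


def fit_change_model(
    cohort: pd.DataFrame,
    predictor: str,
    response_change: str,
    baseline: str | None = None,
    covariates: Sequence[str] = ("age", "sex", "alcohol", "smoking", "pc1", "pc2"),
    log_transform: bool = False,
) -> AssociationResult:
    """Effect of a baseline predictor on 9-year change in a trait.

    The response is the follow-up value adjusted for its baseline (statistically
    equivalent to modelling the change while keeping the baseline in the model,
    up to the baseline coefficient). ``baseline`` defaults to
    ``response_change`` with a ``followup_`` prefix stripped.

    Raises when every follow-up value is missing.
    """
    if baseline is None:
        if not response_change.startswith("followup_"):
            raise ValueError("cannot infer baseline column; pass baseline=")
        baseline = response_change[len("followup_"):]
    if cohort[response_change].dropna().empty:
        raise ValueError(f"all follow-up values of {response_change!r} are missing")
    est = TraitAssociation(
        trait=response_change,
        exposure=predictor,
        covariates=(baseline, *covariates),
        log_transform_trait=log_transform,
        model="linear",
    ).fit(cohort)
    return est.result_()


def fit_obesity_logistic(
    cases_controls: pd.DataFrame,
    copies: str = "cn_amy1a",
    outcome: str = "obesity_case",
    covariates: Sequence[str] = ("age", "sex"),
) -> AssociationResult:
    """Age/sex-adjusted logistic model of obesity on gene copy number.

    Returns the odds ratio per copy with a Wald 95% CI and two-sided P.
    """
    est = TraitAssociation(
        trait=outcome,
        exposure=copies,
        covariates=tuple(covariates),
        model="logistic",
    ).fit(cases_controls)
    return est.result_()
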