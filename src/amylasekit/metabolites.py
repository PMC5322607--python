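"""BMI-linked metabolite panel: censoring-aware imputation and screening.

The panel holds 36 plasma metabolites known to associate with BMI. Values
below the assay detection limit are missing (left-censored); each metabolite's
missing entries are imputed with its smallest detected value, matching the
censoring mechanism. Metabolites with 5% or more missingness are not eligible
for the panel.

The screen fits, per metabolite, a covariate-adjusted linear model with the
metabolite as the dependent variable and an amylase activity as the exposure,
with BMI included in or dropped from the adjustment set, and reports whether
the exposure effect's sign agrees with the metabolite's own BMI effect.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._design import build_design, residualize

__all__ = [
    "METABOLITES",
    "MAX_MISSING_RATE",
    "MinimumImputer",
    "impute_minimum",
    "MetaboliteScreen",
    "metabolite_screen",
]

#: The 36 BMI-associated plasma metabolites in the panel.
METABOLITES = (
    "1,5-anhydroglucitol",
    "1-oleoylglycerophosphocholine (18:1)",
    "2-hydroxybutyrate",
    "2-linoleoylglycerophosphocholine",
    "3-(4-hydroxyphenyl)lactate",
    "3-hydroxyisobutyrate",
    "3-methyl-2-oxobutyrate",
    "3-methyl-2-oxovalerate",
    "4-methyl-2-oxopentanoate",
    "7-alpha-hydroxy-3-oxo-4-cholestenoate",
    "alpha-hydroxyisovalerate",
    "andro steroid monosulfate 2",
    "asparagine",
    "benzoate",
    "butyrylcarnitine",
    "carnitine",
    "gamma-glutamylisoleucine",
    "gamma-glutamyltyrosine",
    "glutamate",
    "glycerol",
    "glycine",
    "hexanoylcarnitine",
    "histidine",
    "isoleucine",
    "isovalerylcarnitine",
    "kynurenine",
    "lactate",
    "lathosterol",
    "leucine",
    "mannose",
    "N-acetylglycine",
    "palmitoyl sphingomyelin",
    "phenylalanine",
    "propionylcarnitine",
    "tyrosine",
    "valine",
)

#: Panel eligibility: per-metabolite missing value rate must stay below 5%.
MAX_MISSING_RATE = 0.05


class MinimumImputer(TransformerMixin, BaseEstimator):
    """Impute left-censored missing values with the observed per-column minimum.

    ``fit`` records each column's smallest detected value in ``minima_``;
    ``transform`` replaces missing entries with it and leaves every observed
    entry untouched. Idempotent by construction. Raises on an all-missing
    column, where no detection limit surrogate exists.
    """

    def fit(self, panel: pd.DataFrame, y=None):
        empty = [c for c in panel.columns if panel[c].dropna().empty]
        if empty:
            raise ValueError(f"all-missing metabolite columns: {empty}")
        self.minima_ = panel.min(axis=0, skipna=True)
        self.missing_rate_ = panel.isna().mean(axis=0)
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        return panel.fillna(self.minima_)


def impute_minimum(panel: pd.DataFrame) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper over :class:`MinimumImputer`."""
    return MinimumImputer().fit(panel).transform(panel)


class MetaboliteScreen(BaseEstimator):
    """Per-metabolite adjusted association with an amylase exposure.

    Parameters
    ----------
    exposure : str
        Cohort column used as exposure (e.g. ``"amy1_activity"``).
    adjust_bmi : bool
        Include BMI in the adjustment set (the screen is typically run both
        ways to separate BMI-mediated from BMI-independent signal).
    covariates : sequence of str
        Adjustment set without BMI; BMI is appended when ``adjust_bmi``.
    log_transform : bool
        Natural-log the metabolite values before fitting (off by default;
        synthetic panel units are arbitrary).

    After ``fit(cohort, panel)``, ``results_`` holds one row per metabolite:
    effect, se, t-based two-sided p, Bonferroni-adjusted p over the panel,
    the metabolite's own adjusted BMI effect, and ``concordant_with_bmi``
    (True when the exposure and BMI effects share sign).
    """

    def __init__(
        self,
        exposure: str = "amy1_activity",
        adjust_bmi: bool = True,
        covariates: Sequence[str] = ("age", "sex", "alcohol", "smoking", "pc1", "pc2"),
        log_transform: bool = False,
    ):
        self.exposure = exposure
        self.adjust_bmi = adjust_bmi
        self.covariates = covariates
        self.log_transform = log_transform

    def _multi_ols(self, data: pd.DataFrame, x_col: str, covs: list[str], Y: np.ndarray):
        """Exposure coefficient for many responses sharing one design (FWL)."""
        C = build_design(data, covs).to_numpy(dtype=float)
        x = data[x_col].astype(float).to_numpy()
        rx = residualize(x, C)
        RY = residualize(Y, C)
        xss = float(rx @ rx)
        if xss <= 1e-12:
            raise ValueError(f"exposure {x_col!r} is collinear with the covariates")
        beta = RY.T @ rx / xss
        dof = len(data) - C.shape[1] - 1
        sse = np.einsum("ij,ij->j", RY, RY) - beta**2 * xss
        se = np.sqrt(np.maximum(sse, 0.0) / dof / xss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        return beta, se, p

    def fit(self, cohort: pd.DataFrame, panel: pd.DataFrame):
        if panel.isna().any().any():
            raise ValueError("panel contains missing values; impute first")
        covs = list(self.covariates) + (["bmi"] if self.adjust_bmi else [])
        data = cohort.loc[panel.index, [self.exposure, "bmi", *self.covariates]]
        keep = data.dropna().index
        data = data.loc[keep]
        Y = panel.loc[keep].to_numpy(dtype=float)
        if self.log_transform:
            if np.any(Y <= 0):
                raise ValueError("log transform requires strictly positive values")
            Y = np.log(Y)

        beta, se, p = self._multi_ols(data, self.exposure, covs, Y)
        # each metabolite's own BMI effect, with the same base adjustment
        bmi_beta, _, _ = self._multi_ols(data, "bmi", list(self.covariates), Y)

        k = panel.shape[1]
        self.results_ = pd.DataFrame(
            {
                "metabolite": panel.columns,
                "n": len(keep),
                "effect": beta,
                "se": se,
                "p": p,
                "p_bonferroni": np.minimum(p * k, 1.0),
                "bmi_effect": bmi_beta,
                "concordant_with_bmi": np.sign(beta) == np.sign(bmi_beta),
            }
        )
        self.n_ = int(len(keep))
        return self


def metabolite_screen(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    exposure: str,
    adjust_bmi: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Run the per-metabolite screen and return the results table."""
    screen = MetaboliteScreen(exposure=exposure, adjust_bmi=adjust_bmi, **kwargs)
    return screen.fit(cohort, panel).results_
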