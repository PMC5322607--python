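"""Fixed-effect inverse-variance meta-analysis.

Pools per-study effect estimates with weights :math:`w_i = 1/\\mathrm{SE}_i^2`,
reports the pooled two-sided P from the normal approximation
:math:`z = \\beta_{pooled}/\\mathrm{SE}_{pooled}`, and quantifies between-study
heterogeneity with Cochran's Q (:math:`\\chi^2_{k-1}` under homogeneity).

Odds-ratio inputs given as OR with a 95% confidence interval are pooled on the
log-OR scale, converting the CI half-width to a standard error under symmetric
normal intervals (``se = (ln(hi) - ln(lo)) / (2 * 1.96)``), then back-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "FixedEffectMeta",
    "fixed_effect_meta",
    "or_meta",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class StudyEstimate:
    """One study's effect estimate (log-OR for binary outcomes)."""

    study: str
    beta: float
    se: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.study!r}: se must be > 0, got {self.se}")


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity diagnostics.

    ``or_pooled``/``or_ci`` are populated only for odds-ratio-scale pooling.
    """

    beta_pooled: float
    se_pooled: float
    p_pooled: float
    q: float
    p_het: float
    k: int
    or_pooled: float | None = None
    or_ci: tuple[float, float] | None = field(default=None)


class FixedEffectMeta(BaseEstimator):
    """Fixed-effect inverse-variance pooling as a fittable estimator.

    Parameters
    ----------
    p_method : {"pooled_z", "stouffer"}
        How the pooled P value is formed. ``"pooled_z"`` (default) uses the
        normal z of the pooled estimate, equivalent to a weighted inverse-normal
        combination with weights proportional to ``1/se``. ``"stouffer"`` is the
        sample-size-weighted inverse-normal variant and requires per-study ``n``.

    Attributes
    ----------
    beta_ : float
        Inverse-variance-weighted pooled effect.
    se_ : float
        Pooled standard error ``1/sqrt(sum(w))``.
    p_ : float
        Two-sided pooled P value.
    q_ : float
        Cochran's Q heterogeneity statistic.
    p_het_ : float
        Heterogeneity P from chi-square with ``k - 1`` df (1.0 when k = 1).
    k_ : int
        Number of studies pooled.
    """

    def __init__(self, p_method: str = "pooled_z"):
        self.p_method = p_method

    def fit(self, beta, se, n=None):
        if self.p_method not in ("pooled_z", "stouffer"):
            raise ValueError(f"unknown p_method {self.p_method!r}")
        beta = np.asarray(beta, dtype=float)
        se = np.asarray(se, dtype=float)
        if beta.ndim != 1 or beta.shape != se.shape:
            raise ValueError("beta and se must be 1-d arrays of equal length")
        if beta.size == 0:
            raise ValueError("at least one study is required")
        if np.any(se <= 0):
            raise ValueError("all standard errors must be > 0")

        w = 1.0 / se**2
        self.k_ = int(beta.size)
        self.beta_ = float(np.sum(w * beta) / np.sum(w))
        self.se_ = float(1.0 / math.sqrt(np.sum(w)))
        if self.p_method == "pooled_z":
            z = self.beta_ / self.se_
        else:
            if n is None:
                raise ValueError("stouffer weighting requires per-study sample sizes")
            n = np.asarray(n, dtype=float)
            zi = beta / se
            z = float(np.sum(np.sqrt(n) * zi) / math.sqrt(np.sum(n)))
        self.p_ = float(2.0 * stats.norm.sf(abs(z)))
        self.q_ = float(np.sum(w * (beta - self.beta_) ** 2))
        self.p_het_ = float(stats.chi2.sf(self.q_, self.k_ - 1)) if self.k_ > 1 else 1.0
        return self

    def result_(self) -> MetaResult:
        return MetaResult(
            beta_pooled=self.beta_,
            se_pooled=self.se_,
            p_pooled=self.p_,
            q=self.q_,
            p_het=self.p_het_,
            k=self.k_,
        )


def fixed_effect_meta(
    studies: Sequence[StudyEstimate], p_method: str = "pooled_z"
) -> MetaResult:
    """Pool study estimates on the linear (beta) scale.

    Thin functional wrapper over :class:`FixedEffectMeta`.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("at least one study is required")
    n = [s.n for s in studies] if all(s.n is not None for s in studies) else None
    est = FixedEffectMeta(p_method=p_method).fit(
        [s.beta for s in studies], [s.se for s in studies], n=n
    )
    return est.result_()


def or_meta(
    studies: Sequence[tuple[float, float, float]], p_method: str = "pooled_z"
) -> MetaResult:
    """Pool odds ratios given as ``(or, ci_low, ci_high)`` triples.

    Converts each study to a log-OR with ``se = (ln hi - ln lo)/(2 * 1.96)``,
    pools with :func:`fixed_effect_meta`, and back-transforms the pooled effect
    and its 95% CI by exponentiation.
    """
    converted = []
    for i, (or_, lo, hi) in enumerate(studies):
        if not (0.0 < lo < or_ < hi):
            raise ValueError(
                f"study {i}: require 0 < ci_low < OR < ci_high, got ({or_}, {lo}, {hi})"
            )
        converted.append(
            StudyEstimate(
                study=f"study_{i}",
                beta=math.log(or_),
                se=(math.log(hi) - math.log(lo)) / (2.0 * _Z95),
            )
        )
    res = fixed_effect_meta(converted, p_method=p_method)
    res.or_pooled = math.exp(res.beta_pooled)
    res.or_ci = (
        math.exp(res.beta_pooled - _Z95 * res.se_pooled),
        math.exp(res.beta_pooled + _Z95 * res.se_pooled),
    )
    return res
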