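"""Droplet digital PCR copy-number estimation.

A ddPCR reaction partitions template molecules into thousands of droplets; the
number of molecules per droplet is Poisson, so the mean occupancy of a channel
is recovered from the fraction of positive droplets as

    lambda = -ln(1 - n_positive / n_droplets).

The diploid copy number of the target relative to a two-copy reference assay is

    CN = 2 * lambda_target / lambda_reference.

Wells with fewer than 7000 accepted droplets fail quality control and are
excluded from downstream analyses rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MIN_DROPLETS",
    "DropletWell",
    "CopyNumberEstimate",
    "SaturationError",
    "ReferenceNegativeError",
    "estimate_copy_number",
    "CopyNumberCaller",
    "parity_statistics",
    "ParitySummary",
    "rank_correlation",
]

#: Minimum accepted droplets per well for a QC pass.
MIN_DROPLETS = 7000


class SaturationError(ValueError):
    """A channel is fully positive, so its Poisson mean is unbounded."""


class ReferenceNegativeError(ValueError):
    """The reference channel has zero positive droplets (CN undefined)."""


@dataclass
class DropletWell:
    """Classified droplet counts for one sample/well."""

    sample_id: str
    n_droplets: int
    n_target_positive: int
    n_ref_positive: int

    def __post_init__(self) -> None:
        for name in ("n_target_positive", "n_ref_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_droplets:
                raise ValueError(
                    f"well {self.sample_id!r}: {name}={v} outside [0, {self.n_droplets}]"
                )


@dataclass
class CopyNumberEstimate:
    sample_id: str
    cn_continuous: float
    cn_integer: int
    qc_pass: bool
    lambda_target: float
    lambda_ref: float
    #: optional 95% CI on cn_continuous (delta method); not used downstream by default
    ci: tuple[float, float] | None = None


def _channel_lambda(n_pos: int, n_droplets: int) -> float:
    return -math.log(1.0 - n_pos / n_droplets)


def estimate_copy_number(
    well: DropletWell,
    min_droplets: int = MIN_DROPLETS,
    with_ci: bool = False,
) -> CopyNumberEstimate:
    """Estimate diploid copy number for one well.

    Raises
    ------
    SaturationError
        If either channel has every droplet positive.
    ReferenceNegativeError
        If the reference channel has no positive droplets.
    """
    if well.n_droplets <= 0:
        raise ValueError(f"well {well.sample_id!r}: n_droplets must be > 0")
    if well.n_target_positive >= well.n_droplets or well.n_ref_positive >= well.n_droplets:
        raise SaturationError(
            f"well {well.sample_id!r}: a channel is fully positive; "
            "occupancy cannot be estimated"
        )
    if well.n_ref_positive == 0:
        raise ReferenceNegativeError(
            f"well {well.sample_id!r}: reference channel has no positive droplets"
        )
    lam_t = _channel_lambda(well.n_target_positive, well.n_droplets)
    lam_r = _channel_lambda(well.n_ref_positive, well.n_droplets)
    cn = 2.0 * lam_t / lam_r
    # numpy rounding is half-to-even, which is the tie-break we document
    cn_int = int(np.round(cn))
    ci = None
    if with_ci:
        # delta method: var(lambda_hat) = p / (n (1 - p)) for p = positive fraction
        n = well.n_droplets
        p_t = well.n_target_positive / n
        p_r = well.n_ref_positive / n
        var_t = p_t / (n * (1.0 - p_t))
        var_r = p_r / (n * (1.0 - p_r))
        rel_var = var_t / lam_t**2 if lam_t > 0 else np.inf
        rel_var += var_r / lam_r**2
        se = cn * math.sqrt(rel_var) if np.isfinite(rel_var) else float("inf")
        z = stats.norm.ppf(0.975)
        ci = (cn - z * se, cn + z * se)
    return CopyNumberEstimate(
        sample_id=well.sample_id,
        cn_continuous=cn,
        cn_integer=cn_int,
        qc_pass=well.n_droplets >= min_droplets,
        lambda_target=lam_t,
        lambda_ref=lam_r,
        ci=ci,
    )


class CopyNumberCaller(TransformerMixin, BaseEstimator):
    """Vectorised copy-number caller over a table of droplet wells.

    Input is a DataFrame with columns ``sample_id, n_droplets,
    n_target_positive, n_ref_positive`` (the well-table dialect written by the
    simulator and by real ddPCR exports). ``transform`` returns one row per
    well with ``cn_continuous``, ``cn_integer``, ``qc_pass``, and the two
    channel occupancies.

    Parameters
    ----------
    min_droplets : int
        QC threshold on accepted droplets (default 7000).
    drop_failed : bool
        If True, QC-failed wells are removed from the output instead of being
        flagged; the number dropped is recorded in ``n_qc_failed_``.
    """

    def __init__(self, min_droplets: int = MIN_DROPLETS, drop_failed: bool = False):
        self.min_droplets = min_droplets
        self.drop_failed = drop_failed

    def fit(self, wells: pd.DataFrame, y=None):
        # stateless: fit only validates the input schema
        required = {"sample_id", "n_droplets", "n_target_positive", "n_ref_positive"}
        missing = required - set(wells.columns)
        if missing:
            raise ValueError(f"well table is missing columns: {sorted(missing)}")
        self.n_features_in_ = wells.shape[1]
        return self

    def transform(self, wells: pd.DataFrame) -> pd.DataFrame:
        self.fit(wells)
        rows = []
        for w in wells.itertuples(index=False):
            est = estimate_copy_number(
                DropletWell(
                    sample_id=str(w.sample_id),
                    n_droplets=int(w.n_droplets),
                    n_target_positive=int(w.n_target_positive),
                    n_ref_positive=int(w.n_ref_positive),
                ),
                min_droplets=self.min_droplets,
            )
            rows.append(
                (est.sample_id, est.cn_continuous, est.cn_integer, est.qc_pass,
                 est.lambda_target, est.lambda_ref)
            )
        out = pd.DataFrame(
            rows,
            columns=["sample_id", "cn_continuous", "cn_integer", "qc_pass",
                     "lambda_target", "lambda_ref"],
        )
        self.n_qc_failed_ = int((~out["qc_pass"]).sum())
        if self.drop_failed:
            out = out[out["qc_pass"]].reset_index(drop=True)
        return out


@dataclass
class ParitySummary:
    """Even-copy excess and cross-gene parity concordance."""

    n: int
    even_fraction_amy1: float
    concordant_fraction: float
    p_even_excess: float


def parity_statistics(cn_pairs: Iterable[tuple[int, int]]) -> ParitySummary:
    """Summarise copy-number parity over ``(cn_amy1a, cn_amy2a)`` pairs.

    Returns the fraction of even AMY1A copy numbers, the fraction of pairs
    whose two copy numbers share parity, and an exact two-sided binomial test
    of the even fraction against 0.5.
    """
    pairs = np.asarray(list(cn_pairs), dtype=int)
    if pairs.size == 0:
        raise ValueError("cn_pairs must be non-empty")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("cn_pairs must be a sequence of (cn_amy1a, cn_amy2a) pairs")
    if np.any(pairs <= 0):
        raise ValueError("copy numbers must be positive integers")
    even1 = pairs[:, 0] % 2 == 0
    concordant = (pairs[:, 0] % 2) == (pairs[:, 1] % 2)
    n = pairs.shape[0]
    p_even = stats.binomtest(int(even1.sum()), n, 0.5).pvalue
    return ParitySummary(
        n=n,
        even_fraction_amy1=float(even1.mean()),
        concordant_fraction=float(concordant.mean()),
        p_even_excess=float(p_even),
    )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Squared Spearman rank correlation with its two-sided P value.

    Ranks use midranks for ties. Raises on constant input, where the
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic**2), float(res.pvalue)
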