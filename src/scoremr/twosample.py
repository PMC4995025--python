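"""Two-sample Mendelian randomization from summary statistics.

Per instrument SNP the Wald ratio is ``b_causal = b_YG / b_XG`` (outcome
log-OR per unit of exposure) with a delta-method standard error

    se = sqrt( S_YG^2 / b_XG^2  +  S_XG^2 * b_YG^2 / b_XG^4 ).

Instruments are combined by inverse-variance weighting (IVW); directional
pleiotropy is probed by Egger regression, a 1/S_YG^2-weighted regression of
b_YG on b_XG with a free intercept, after orienting every instrument so that
b_XG > 0.  A non-zero intercept indicates a systematic direct path from the
instruments to the outcome that bypasses the exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .meta import MetaResult, fixed_effects_meta
from .sumstats import HarmonizedPair

__all__ = [
    "WaldEstimate",
    "EggerResult",
    "wald_ratio",
    "ivw_combine",
    "egger_regression",
    "funnel_data",
]

#: |b_XG| / S_XG below which an instrument is flagged weak (retained regardless)
WEAK_INSTRUMENT_Z = 2.0


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal log-OR per exposure unit, with its standard error."""

    rsid: str
    beta_causal: float
    se_causal: float
    weak: bool = False


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept (pleiotropy) and slope (causal estimate)."""

    intercept: float
    se_intercept: float
    p_intercept: float
    slope: float
    se_slope: float
    p_slope: float
    n_snps: int


def wald_ratio(pair: HarmonizedPair, se_mode: str = "delta") -> WaldEstimate:
    """Causal estimate for one harmonized instrument.

    ``se_mode='delta'`` uses the two-term delta-method SE above;
    ``'first_order'`` drops the exposure-uncertainty term (S_XG treated as 0),
    the conventional weighting for IVW.
    """
    if not pair.kept:
        raise DomainError(f"{pair.snp.rsid}: pair was dropped during harmonization")
    bxg = pair.snp.beta_exposure
    if bxg == 0:
        raise DomainError(f"{pair.snp.rsid}: beta_exposure is 0, Wald ratio undefined")
    sxg = pair.snp.se_exposure
    byg = pair.outcome.beta_outcome
    syg = pair.outcome.se_outcome
    beta = byg / bxg
    if se_mode == "delta":
        se = math.sqrt(syg**2 / bxg**2 + sxg**2 * byg**2 / bxg**4)
    elif se_mode == "first_order":
        se = syg / abs(bxg)
    else:
        raise DomainError(f"unknown se_mode {se_mode!r}")
    if se == 0:
        raise DomainError(f"{pair.snp.rsid}: zero standard error")
    return WaldEstimate(
        rsid=pair.snp.rsid,
        beta_causal=beta,
        se_causal=se,
        weak=abs(bxg) / sxg < WEAK_INSTRUMENT_Z,
    )


def ivw_combine(estimates: Sequence[WaldEstimate], level: float = 0.95) -> MetaResult:
    """Inverse-variance weighted combination of per-SNP causal estimates."""
    if len(estimates) == 0:
        raise DomainError("no estimates to combine")
    return fixed_effects_meta(
        [e.beta_causal for e in estimates],
        [e.se_causal for e in estimates],
        level=level,
    )


def egger_regression(
    pairs: Sequence[HarmonizedPair], constrain_intercept: bool = False
) -> EggerResult:
    """Weighted Egger regression over kept instruments (needs >= 3).

    ``constrain_intercept=True`` forces the line through the origin; the slope
    then coincides with the first-order IVW estimate (useful as a cross-check,
    not a pleiotropy test).  P-values are two-sided normal.
    """
    kept = [p for p in pairs if p.kept and p.snp.beta_exposure != 0]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"Egger regression needs >= 3 usable instruments, got {len(kept)}"
        )
    bxg = np.array([p.snp.beta_exposure for p in kept])
    byg = np.array([p.outcome.beta_outcome for p in kept])
    syg = np.array([p.outcome.se_outcome for p in kept])
    # orient all instruments to positive exposure effect
    sign = np.sign(bxg)
    x = bxg * sign
    y = byg * sign
    w = 1.0 / syg**2

    design = x[:, None] if constrain_intercept else sm.add_constant(x)
    fit = sm.WLS(y, design, weights=w).fit()
    if constrain_intercept:
        slope, se_slope = float(fit.params[0]), float(fit.bse[0])
        intercept = se_intercept = 0.0
        p_intercept = float("nan")
    else:
        (intercept, slope) = (float(fit.params[0]), float(fit.params[1]))
        (se_intercept, se_slope) = (float(fit.bse[0]), float(fit.bse[1]))
        p_intercept = float(2.0 * stats.norm.sf(abs(intercept / se_intercept)))
    p_slope = float(2.0 * stats.norm.sf(abs(slope / se_slope)))
    return EggerResult(
        intercept=intercept,
        se_intercept=se_intercept,
        p_intercept=p_intercept,
        slope=slope,
        se_slope=se_slope,
        p_slope=p_slope,
        n_snps=len(kept),
    )


def funnel_data(estimates: Sequence[WaldEstimate]) -> pd.DataFrame:
    """Per-SNP (causal estimate, precision) table for external funnel plotting."""
    if len(estimates) == 0:
        raise DomainError("no estimates")
    return pd.DataFrame(
        {
            "rsid": [e.rsid for e in estimates],
            "beta_causal": [e.beta_causal for e in estimates],
            "precision": [1.0 / e.se_causal for e in estimates],
        }
    )
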