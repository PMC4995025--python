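"""Genetic score construction and calibration to exposure units.

The weighted score for individual *j* is ``GS_j = sum_i beta_i * d_ij`` where
``beta_i`` is the externally reported per-allele exposure effect and ``d_ij``
the effect-allele dosage in [0, 2].  Because external weights are on an
arbitrary scale, the score is rescaled to exposure units (here kg/m^2) by
ordinary least squares of observed BMI on GS *among controls*:

    calibrated_j = b0 + b1 * GS_j

The calibrated score is a linear transform of GS (correlation 1), so logistic
coefficients on it can be reported per natural unit, e.g. per 5 kg/m^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigError, DegenerateFitError, DomainError
from .sumstats import SnpRecord

__all__ = [
    "compute_gs",
    "CalibrationResult",
    "calibrate_score",
    "variance_explained",
    "categorize_score",
]

logger = logging.getLogger(__name__)


def compute_gs(
    dosages: pd.DataFrame,
    panel: Sequence[SnpRecord],
    weighted: bool = True,
    missing_policy: str = "impute_eaf",
) -> pd.Series:
    """Per-individual raw genetic score from an individuals x SNPs dosage table.

    ``missing_policy='impute_eaf'`` replaces missing dosages (and entirely
    absent panel columns) with the Hardy-Weinberg expectation ``2 * eaf``;
    ``'error'`` refuses missing data.  Individuals with no observed dosage at
    all are returned as NaN and logged, so downstream fits can exclude them.
    """
    if missing_policy not in ("impute_eaf", "error"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")
    rsids = [r.rsid for r in panel]
    weights = np.array([r.beta_exposure for r in panel]) if weighted else np.ones(len(panel))

    mat = pd.DataFrame(index=dosages.index, columns=rsids, dtype=float)
    present = [r for r in rsids if r in dosages.columns]
    mat[present] = dosages[present].astype(float)
    absent = [r.rsid for r in panel if r.rsid not in dosages.columns]
    if absent:
        if missing_policy == "error":
            raise ConfigError(f"dosage columns missing for panel SNP(s) {absent}")
        logger.warning("imputing %d absent dosage column(s) with 2*eaf", len(absent))

    values = mat.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmin(values, initial=0.0) < 0 or np.nanmax(values, initial=0.0) > 2:
            raise DomainError("dosages must lie within [0, 2]")

    all_missing = np.all(np.isnan(values), axis=1)
    if missing_policy == "error" and np.isnan(values).any():
        raise DomainError("missing dosages present under missing_policy='error'")

    expectation = np.array([2.0 * r.eaf for r in panel])
    filled = np.where(np.isnan(values), expectation, values)
    scores = filled @ weights
    scores[all_missing] = np.nan
    if all_missing.any():
        logger.warning(
            "%d individual(s) with no observed dosages excluded (NaN score)",
            int(all_missing.sum()),
        )
    return pd.Series(scores, index=dosages.index, name="gs_raw")


@dataclass(frozen=True)
class CalibrationResult:
    """OLS rescaling of the raw score to exposure units (controls only)."""

    beta0: float  # intercept, kg/m^2
    beta1: float  # slope on the raw score
    n: int

    def apply(self, gs_raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
        return self.beta0 + self.beta1 * gs_raw


def calibrate_score(gs_raw: pd.Series, bmi: pd.Series) -> CalibrationResult:
    """Regress observed BMI on the raw score (controls) and return the line.

    Requires at least three complete pairs and non-zero score variance.
    """
    x = np.asarray(gs_raw, dtype=float)
    y = np.asarray(bmi, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateFitError(f"need >= 3 complete (score, BMI) pairs, got {x.size}")
    if np.var(x) == 0:
        raise DegenerateFitError("zero score variance: calibration slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    beta0, beta1 = model.params
    return CalibrationResult(beta0=float(beta0), beta1=float(beta1), n=int(x.size))


def variance_explained(gs_raw: pd.Series, bmi: pd.Series) -> float:
    """Fraction of BMI variance explained by the score (regression R^2)."""
    x = np.asarray(gs_raw, dtype=float)
    y = np.asarray(bmi, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateFitError(f"need >= 3 complete (score, BMI) pairs, got {x.size}")
    if np.var(x) == 0:
        raise DegenerateFitError("zero score variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def categorize_score(
    calibrated: pd.Series | np.ndarray,
    cutpoints: Sequence[float] = (25.5, 26.0, 26.5),
    labels: Sequence[str] | None = None,
) -> pd.Categorical:
    """Bin calibrated scores into ordered groups; the lowest bin is reference.

    Bins are left-closed, right-open except the final open-ended group:
    with the default cutpoints, ``[-inf, 25.5) [25.5, 26.0) [26.0, 26.5)
    [26.5, inf)``, so a value exactly at a cutpoint belongs to the bin above.
    """
    cuts = list(cutpoints)
    if not cuts:
        raise ConfigError("cutpoints must be non-empty")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ConfigError(f"cutpoints must be strictly ascending: {cuts}")
    if labels is None:
        labels = (
            [f"<{cuts[0]}"]
            + [f"[{a},{b})" for a, b in zip(cuts, cuts[1:])]
            + [f">={cuts[-1]}"]
        )
    if len(labels) != len(cuts) + 1:
        raise ConfigError("need exactly len(cutpoints)+1 labels")
    return pd.cut(
        np.asarray(calibrated, dtype=float),
        bins=[-np.inf] + cuts + [np.inf],
        right=False,
        labels=list(labels),
        ordered=True,
    )
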