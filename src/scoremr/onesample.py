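"""One-sample instrumental-variable analysis via logistic regression.

The calibrated genetic score (genetically predicted BMI, kg/m^2) is entered
into a maximum-likelihood logistic model of case status, adjusted for
covariates (age, genetic principal components, study site, optionally
reproductive and lifestyle factors).  Effects are reported per 5 kg/m^2 as
``exp(5 b)`` with Wald confidence intervals from the information matrix.
Stratified fits and per-study fits reuse the same machinery, with
between-stratum heterogeneity assessed by Cochran's Q on the stratum betas
and per-study results combined by fixed-effects meta-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateFitError, DomainError, InsufficientDataError
from .meta import MetaResult, cochran_q, fixed_effects_meta
from .score import categorize_score

__all__ = [
    "AssocEstimate",
    "fit_score_outcome",
    "stratified_fit",
    "per_study_meta",
    "estimates_to_frame",
    "BASIC_COVARIATES",
    "EXTENDED_COVARIATES",
]

logger = logging.getLogger(__name__)

#: adjustment profile mirroring the primary model: age, 8 PCs, study site
BASIC_COVARIATES = ["age"] + [f"pc{i}" for i in range(1, 9)] + ["study"]
#: extended profile with reproductive and lifestyle risk factors added
EXTENDED_COVARIATES = BASIC_COVARIATES + [
    "age_menarche",
    "parity",
    "contraceptive_use",
    "ht_use",
    "breastfeeding",
    "smoking",
]

#: strata below this many individuals are skipped rather than fitted
MIN_STRATUM_SIZE = 100


@dataclass(frozen=True)
class AssocEstimate:
    """Association of the calibrated score with case status in one group."""

    label: str
    n: int
    beta: float  # log-OR per unit (kg/m^2) of calibrated score
    se: float
    p: float
    per: float = 5.0
    level: float = 0.95

    @property
    def or_per(self) -> float:
        """OR per ``per`` units, exp(per * beta)."""
        return math.exp(self.per * self.beta)

    @property
    def ci_per(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        return (
            math.exp(self.per * (self.beta - z * self.se)),
            math.exp(self.per * (self.beta + z * self.se)),
        )


def _design_matrix(
    pheno: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """Intercept + covariates; categorical/object columns become dummies."""
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        raise DomainError(f"covariate column(s) absent from table: {missing}")
    parts = []
    for c in covariates:
        col = pheno[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(c))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=pheno.index)
    X.insert(0, "const", 1.0)
    return X


def _fit_logit(y: pd.Series, X: pd.DataFrame, label: str) -> sm.Logit:
    try:
        fit = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit(
            disp=0, maxiter=100
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise DegenerateFitError(f"{label}: logistic fit failed ({exc})") from exc
    if not fit.mle_retvals.get("converged", True):
        raise DegenerateFitError(f"{label}: logistic fit did not converge")
    return fit


def fit_score_outcome(
    pheno: pd.DataFrame,
    score: pd.Series,
    covariates: Sequence[str] = (),
    form: str = "continuous",
    per: float = 5.0,
    cutpoints: Sequence[float] = (25.5, 26.0, 26.5),
    label: str = "all",
    level: float = 0.95,
) -> AssocEstimate | list[AssocEstimate]:
    """Logistic fit of case status on the calibrated score.

    ``form='continuous'`` returns one :class:`AssocEstimate` for the score
    coefficient; ``'categorical'`` bins the score at ``cutpoints`` and returns
    one estimate per non-reference bin against the lowest bin.
    Rows with a missing score are excluded.
    """
    if "case_status" not in pheno.columns:
        raise DomainError("phenotype table lacks 'case_status'")
    data = pheno.copy()
    data["_score"] = np.asarray(score, dtype=float)
    data = data[np.isfinite(data["_score"])]
    y = data["case_status"].astype(float)
    if y.nunique() < 2:
        raise DomainError(f"{label}: outcome has a single class")

    X_cov = _design_matrix(data, covariates)
    if form == "continuous":
        X = pd.concat([X_cov.iloc[:, :1], data["_score"].rename("score"), X_cov.iloc[:, 1:]], axis=1)
        fit = _fit_logit(y, X, label)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        return _estimate(label, len(data), beta, se, per, level)
    if form == "categorical":
        groups = categorize_score(data["_score"], cutpoints=cutpoints)
        dummies = pd.get_dummies(groups, dtype=float).iloc[:, 1:]  # drop reference
        dummies.index = data.index
        X = pd.concat([X_cov.iloc[:, :1], dummies, X_cov.iloc[:, 1:]], axis=1)
        fit = _fit_logit(y, X, label)
        out = []
        for j, name in enumerate(dummies.columns):
            beta, se = float(fit.params[1 + j]), float(fit.bse[1 + j])
            out.append(_estimate(str(name), int(dummies[name].sum() + 0.5), beta, se, 1.0, level))
        return out
    raise DomainError(f"unknown form {form!r}")


def _estimate(label, n, beta, se, per, level) -> AssocEstimate:
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return AssocEstimate(label=label, n=n, beta=beta, se=se, p=p, per=per, level=level)


@dataclass
class StratifiedResult:
    estimates: dict[str, AssocEstimate] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    het_q: float | None = None
    het_df: int | None = None
    het_p: float | None = None


def stratified_fit(
    pheno: pd.DataFrame,
    score: pd.Series,
    covariates: Sequence[str],
    stratum_var: str,
    per: float = 5.0,
    min_stratum: int = MIN_STRATUM_SIZE,
) -> StratifiedResult:
    """Independent fits per stratum plus a Cochran's Q heterogeneity test.

    Strata below ``min_stratum`` individuals (or failing the fit
    preconditions) are skipped with a warning.  With fewer than two fitted
    strata, heterogeneity is reported as absent (None).
    """
    if stratum_var not in pheno.columns:
        raise DomainError(f"stratum column {stratum_var!r} absent")
    result = StratifiedResult()
    score = pd.Series(np.asarray(score, dtype=float), index=pheno.index)
    for value, sub in pheno.groupby(stratum_var, observed=True, dropna=True):
        name = str(value)
        if len(sub) < min_stratum:
            logger.warning("stratum %s below minimum size (%d), skipped", name, len(sub))
            result.skipped.append(name)
            continue
        try:
            est = fit_score_outcome(
                sub, score.loc[sub.index], covariates, per=per, label=name
            )
        except (DomainError, DegenerateFitError) as exc:
            logger.warning("stratum %s skipped: %s", name, exc)
            result.skipped.append(name)
            continue
        result.estimates[name] = est
    if len(result.estimates) >= 2:
        ests = list(result.estimates.values())
        q, df, p = cochran_q([e.beta for e in ests], [e.se for e in ests])
        result.het_q, result.het_df, result.het_p = q, df, p
    return result


@dataclass
class PerStudyResult:
    estimates: dict[str, AssocEstimate]
    summary: MetaResult
    skipped: list[str]


def per_study_meta(
    pheno: pd.DataFrame,
    score: pd.Series,
    covariates: Sequence[str],
    study_var: str = "study",
    per: float = 5.0,
    min_study: int = MIN_STRATUM_SIZE,
) -> PerStudyResult:
    """Fit each study separately and combine by fixed-effects meta-analysis.

    ``covariates`` should not include the study indicator itself (it is the
    grouping variable); any occurrence is removed before the per-study fits.
    """
    covs = [c for c in covariates if c != study_var]
    strat = stratified_fit(pheno, score, covs, study_var, per=per, min_stratum=min_study)
    if not strat.estimates:
        raise InsufficientDataError("all studies skipped; nothing to combine")
    ests = list(strat.estimates.values())
    summary = fixed_effects_meta([e.beta for e in ests], [e.se for e in ests])
    return PerStudyResult(estimates=strat.estimates, summary=summary, skipped=strat.skipped)


def estimates_to_frame(
    estimates: Sequence[AssocEstimate], model_profile: str = "basic"
) -> pd.DataFrame:
    """Flatten estimates to the exported TSV layout."""
    rows = []
    for e in estimates:
        lo, hi = e.ci_per
        rows.append(
            {
                "label": e.label,
                "n": e.n,
                "beta": e.beta,
                "se": e.se,
                "or_per": e.or_per,
                "ci_low": lo,
                "ci_high": hi,
                "p": e.p,
                "per": e.per,
                "model_profile": model_profile,
            }
        )
    return pd.DataFrame(rows)
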