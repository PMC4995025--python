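"""Fixed-effects inverse-variance meta-analysis and heterogeneity statistics.

With estimates ``b_j`` and standard errors ``s_j``, weights are
``w_j = 1/s_j^2``; the combined estimate is ``sum(w b)/sum(w)`` with standard
error ``sum(w)^{-1/2}``.  Cochran's Q, ``sum w_j (b_j - b_bar)^2``, is referred
to a chi-square with k-1 degrees of freedom.  The same machinery serves
per-study combination of one-sample fits, stratum-heterogeneity tests, and
row-wise combination of per-SNP results across consortia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "MetaResult",
    "fixed_effects_meta",
    "cochran_q",
    "combine_consortia",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance-combined estimate with heterogeneity diagnostics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    q_df: int
    q_p: float
    k: int
    level: float = 0.95

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _validate(betas, ses) -> tuple[np.ndarray, np.ndarray]:
    b = np.atleast_1d(np.asarray(betas, dtype=float))
    s = np.atleast_1d(np.asarray(ses, dtype=float))
    if b.shape != s.shape:
        raise DomainError(f"length mismatch: {b.shape} betas vs {s.shape} ses")
    if b.size == 0:
        raise DomainError("empty input")
    if not np.all(s > 0) or not np.all(np.isfinite(s)) or not np.all(np.isfinite(b)):
        raise DomainError("all estimates must be finite with positive se")
    return b, s


def fixed_effects_meta(betas, ses, level: float = 0.95) -> MetaResult:
    """Combine estimates under a fixed (common) effect model."""
    b, s = _validate(betas, ses)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    if b.size >= 2:
        q, q_df, q_p = cochran_q(b, s)
    else:
        q, q_df, q_p = 0.0, 0, float("nan")
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        p=p,
        q=q,
        q_df=q_df,
        q_p=q_p,
        k=int(b.size),
        level=level,
    )


def cochran_q(betas, ses) -> tuple[float, int, float]:
    """Heterogeneity Q, degrees of freedom, and chi-square p-value (k >= 2)."""
    b, s = _validate(betas, ses)
    if b.size < 2:
        raise InsufficientDataError("Cochran's Q needs at least 2 estimates")
    w = 1.0 / s**2
    b_bar = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - b_bar) ** 2))
    df = int(b.size - 1)
    return q, df, float(stats.chi2.sf(q, df))


def combine_consortia(
    source_a: pd.DataFrame, source_b: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Row-wise fixed-effects combination of two per-SNP estimate tables.

    Each input needs columns ``rsid``, ``beta``, ``se``.  SNPs present in only
    one source are passed through with ``flag='unreplicated'``.  The result is
    order-symmetric in its inputs (sorted by rsid appearance in a then b).
    """
    for name, df in (("a", source_a), ("b", source_b)):
        missing = {"rsid", "beta", "se"} - set(df.columns)
        if missing:
            raise DomainError(f"source {name} missing column(s) {sorted(missing)}")
        if df["rsid"].duplicated().any():
            dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
            raise DomainError(f"duplicate rsid {dup!r} in source {name}")
    a = source_a.set_index("rsid")
    b = source_b.set_index("rsid")
    rsids = sorted(set(a.index) | set(b.index))
    rows = []
    z = stats.norm.ppf(0.5 + level / 2.0)
    for rsid in rsids:
        in_a, in_b = rsid in a.index, rsid in b.index
        if in_a and in_b:
            res = fixed_effects_meta(
                [a.at[rsid, "beta"], b.at[rsid, "beta"]],
                [a.at[rsid, "se"], b.at[rsid, "se"]],
                level=level,
            )
            beta, se, q_p, flag = res.beta, res.se, res.q_p, "combined"
        else:
            src = a if in_a else b
            beta, se = float(src.at[rsid, "beta"]), float(src.at[rsid, "se"])
            q_p, flag = float("nan"), "unreplicated"
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        rows.append(
            {
                "rsid": rsid,
                "beta_combined": beta,
                "se_combined": se,
                "or": math.exp(beta),
                "ci_low": math.exp(beta - z * se),
                "ci_high": math.exp(beta + z * se),
                "p": p,
                "q_p": q_p,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise DomainError("m must be a positive count")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    return alpha / m
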