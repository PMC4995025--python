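"""Synthetic cohorts and two-sample summary statistics for genetic-score MR.

The generator emulates the statistical structure a BMI / breast-cancer MR
analysis assumes:

* a panel of independent biallelic SNPs in Hardy-Weinberg equilibrium, with
  per-allele exposure effects rescaled so the true score explains a target
  fraction of exposure variance (default 1.23%, the fraction the weighted
  score explained among consortium controls);
* exposure built as  mean + centred score + confounder + Gaussian noise;
* binary case status from a logistic model in the exposure and confounder,
  with the intercept solved numerically so the expected case fraction hits a
  target (emulating a balanced case-control sample);
* optional directional pleiotropy: direct SNP-to-outcome log-OR effects that
  bypass the exposure, which Egger regression should detect;
* two-sample designs: exposure and outcome studies drawn independently (no
  sample overlap), with per-SNP marginal estimates computed by single-SNP
  regressions inside each simulated sample.

A shared confounder (affecting both exposure and outcome) is on by default:
it biases a naive exposure-outcome regression while leaving the genetic
instruments valid, which is the point of the design.

Randomness uses one root seed with fixed per-operation substreams, so e.g.
enlarging the panel does not perturb phenotype draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy import stats

from .exceptions import ConfigError, DomainError
from .sumstats import OutcomeAssociation, SnpRecord

__all__ = [
    "SimConfig",
    "CohortTable",
    "simulate_panel",
    "simulate_cohort",
    "simulate_sumstats",
]

# substream codes (root seed is paired with one of these per draw stage)
_PANEL, _GENO, _PHENO, _COVAR, _OUTCOME, _EXPO_STUDY, _OUT_STUDY = range(1, 8)

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generative parameters; defaults mirror the emulated study design."""

    n_individuals: int = 88_807
    n_cases_target: int = 46_325
    n_snps: int = 84
    eaf_range: tuple[float, float] = (0.05, 0.95)
    #: fraction of exposure variance explained by the true score
    r2_target: float = 0.0123
    bmi_mean: float = 26.4  # kg/m^2
    bmi_sd: float = 4.5  # kg/m^2
    #: true causal log-OR per kg/m^2 of exposure (default: OR 0.65 per 5)
    theta: float = math.log(0.65) / 5.0
    #: confounder effect on exposure (kg/m^2 per SD) and on outcome (log-OR per SD)
    confounder_bmi: float = 0.9
    confounder_outcome: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_studies: int = 5
    site_effect_sd: float = 0.1  # log-OR spread of study-site intercepts
    strata_frac: dict[str, float] = field(
        default_factory=lambda: {
            "postmenopausal": 0.65,
            "ht_ever": 0.5,
            "er_pos": 0.78,
            "pr_pos": 0.70,
        }
    )
    mask_case_bmi: bool = True  # exposure measured post-diagnosis is unusable
    hard_calls: bool = True  # dosages in {0,1,2}; False adds imputation noise
    allow_palindromic: bool = False
    n_discovery: int = 339_224  # discovery-GWAS size backing the panel SEs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_target < 1.0:
            raise ConfigError(f"r2_target {self.r2_target} outside [0, 1)")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(f"eaf_range {self.eaf_range} must satisfy 0 < lo < hi < 1")
        if not 0 < self.n_cases_target < self.n_individuals:
            raise ConfigError("n_cases_target must lie strictly between 0 and n_individuals")
        for k, v in self.strata_frac.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"strata fraction {k}={v} outside [0, 1]")


def _rng(seed: int, code: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(code)])


@dataclass
class CohortTable:
    """Individual-level data: dosage matrix plus phenotype/covariate table."""

    dosages: pd.DataFrame  # individuals x rsids
    pheno: pd.DataFrame  # case_status, bmi, covariates, strata

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.dosages.to_csv(path / "dosages.tsv", sep="\t", index_label="individual_id")
        self.pheno.to_csv(path / "pheno.tsv", sep="\t", index_label="individual_id")

    @classmethod
    def from_dir(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        dosages = pd.read_csv(path / "dosages.tsv", sep="\t", index_col="individual_id")
        pheno = pd.read_csv(path / "pheno.tsv", sep="\t", index_col="individual_id")
        return cls(dosages=dosages, pheno=pheno)


def simulate_panel(config: SimConfig) -> list[SnpRecord]:
    """Draw an instrument panel whose true score hits ``r2_target``.

    Frequencies are uniform on ``eaf_range``.  Each SNP receives a share of
    the target score variance drawn uniformly within a three-fold band, and
    its per-allele effect is ``b_i = sqrt(share_i * r2 * sd^2 / het_i)`` with
    ``het_i = 2 f_i (1 - f_i)``, so the Hardy-Weinberg score variance equals
    ``r2_target * bmi_sd^2`` exactly.  Keeping every share bounded away from
    zero emulates significance ascertainment: instrument panels contain only
    variants that cleared a genome-wide threshold in discovery, so none has a
    near-zero effect.  Effect alleles are oriented exposure-increasing (as
    discovery GWAS report them); reported SEs correspond to a marginal
    regression in a discovery study of ``n_discovery`` individuals.
    """
    rng = _rng(config.seed, _PANEL)
    s = config.n_snps
    if s < 1:
        raise ConfigError("n_snps must be >= 1")
    eaf = rng.uniform(*config.eaf_range, size=s)
    het = 2.0 * eaf * (1.0 - eaf)
    target_var = config.r2_target * config.bmi_sd**2
    shares = rng.uniform(0.5, 1.5, size=s)
    shares /= shares.sum()
    betas = np.sqrt(shares * target_var / het)  # zero when r2_target == 0
    pairs = _NONPALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if config.allow_palindromic else [])
    allele_idx = rng.integers(0, len(pairs), size=s)
    resid_sd = config.bmi_sd * math.sqrt(max(1.0 - config.r2_target, 1e-12))
    ses = resid_sd / np.sqrt(config.n_discovery * het)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(betas) / ses), 1e-300, 1.0)
    records = []
    for i in range(s):
        ea, oa = pairs[allele_idx[i]]
        records.append(
            SnpRecord(
                rsid=f"rs{1_000_000 + i}",
                chrom=str(i % 22 + 1),
                pos=100_000 + 10_000 * i,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[i]),
                beta_exposure=float(betas[i]),
                se_exposure=float(ses[i]),
                p_exposure=float(pvals[i]),
            )
        )
    return records


def _draw_genotypes(
    rng: np.random.Generator, eaf: np.ndarray, n: int, hard_calls: bool
) -> np.ndarray:
    """HWE genotypes as n x S dosages (two Bernoulli draws per individual)."""
    u1 = rng.random((n, eaf.size), dtype=np.float32)
    u2 = rng.random((n, eaf.size), dtype=np.float32)
    g = (u1 < eaf).astype(np.int8) + (u2 < eaf).astype(np.int8)
    if hard_calls:
        return g
    noise = rng.normal(0.0, 0.15, size=g.shape)
    return np.clip(g + noise, 0.0, 2.0).astype(np.float32)


def _noise_sd(config: SimConfig, betas: np.ndarray, eaf: np.ndarray) -> float:
    var_score = float(np.sum(betas**2 * 2.0 * eaf * (1.0 - eaf)))
    resid = config.bmi_sd**2 - var_score - config.confounder_bmi**2
    if resid <= 0:
        raise ConfigError(
            "bmi_sd too small for the requested r2_target and confounder strength"
        )
    return math.sqrt(resid)


def _solve_intercept(linear: np.ndarray, target_frac: float) -> float:
    """Logistic intercept giving the requested expected case fraction."""
    def f(a: float) -> float:
        return float(np.mean(expit(a + linear))) - target_frac

    try:
        return brentq(f, -40.0, 40.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - bounded-search failure
        raise DomainError(f"case fraction {target_frac} unreachable") from exc


def simulate_cohort(
    config: SimConfig, panel: Sequence[SnpRecord] | None = None
) -> CohortTable:
    """One-sample cohort: dosages, exposure, case status, covariates, strata.

    Case BMI is masked by default (most emulated studies measured BMI after
    diagnosis, so only control BMI is usable for score calibration).
    """
    if panel is None:
        panel = simulate_panel(config)
    eaf = np.array([r.eaf for r in panel])
    betas = np.array([r.beta_exposure for r in panel])
    n = config.n_individuals

    g = _draw_genotypes(_rng(config.seed, _GENO), eaf, n, config.hard_calls)
    score = g.astype(np.float64) @ betas
    score_mean = float(np.sum(betas * 2.0 * eaf))

    rng_ph = _rng(config.seed, _PHENO)
    confounder = rng_ph.standard_normal(n)
    noise = rng_ph.standard_normal(n) * _noise_sd(config, betas, eaf)
    bmi = config.bmi_mean + (score - score_mean) + config.confounder_bmi * confounder + noise

    rng_cov = _rng(config.seed, _COVAR)
    age = rng_cov.normal(57.0, 8.0, size=n)
    pcs = rng_cov.standard_normal((n, 8))
    site = rng_cov.integers(0, config.n_studies, size=n)
    site_effects = rng_cov.normal(0.0, config.site_effect_sd, size=config.n_studies)

    rng_out = _rng(config.seed, _OUTCOME)
    linear = config.theta * bmi + config.confounder_outcome * confounder + site_effects[site]
    alpha = _solve_intercept(linear, config.n_cases_target / config.n_individuals)
    case = (rng_out.random(n) < expit(alpha + linear)).astype(np.int8)

    post = rng_out.random(n) < config.strata_frac["postmenopausal"]
    ht = np.where(
        post,
        np.where(rng_out.random(n) < config.strata_frac["ht_ever"], "ever", "never"),
        None,
    )
    is_case = case == 1
    er = np.where(
        is_case,
        np.where(rng_out.random(n) < config.strata_frac["er_pos"], "pos", "neg"),
        None,
    )
    pr = np.where(
        is_case,
        np.where(rng_out.random(n) < config.strata_frac["pr_pos"], "pos", "neg"),
        None,
    )

    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="individual_id")
    dosages = pd.DataFrame(g, index=ids, columns=[r.rsid for r in panel])
    bmi_obs = bmi.copy()
    if config.mask_case_bmi:
        bmi_obs[is_case] = np.nan
    pheno = pd.DataFrame(
        {
            "case_status": case.astype(int),
            "bmi": bmi_obs,
            "age": age,
            **{f"pc{i + 1}": pcs[:, i] for i in range(8)},
            "study": [f"study_{k + 1:02d}" for k in site],
            "menopause": np.where(post, "post", "pre"),
            "ht_use": ht,
            "er": er,
            "pr": pr,
        },
        index=ids,
    )
    return CohortTable(dosages=dosages, pheno=pheno)


def _per_snp_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized single-SNP OLS slopes and SEs of y on each dosage column."""
    n = y.size
    s1 = g.sum(axis=0, dtype=np.float64)
    s2 = (g.astype(np.int64) ** 2).sum(axis=0) if g.dtype == np.int8 else (g**2).sum(
        axis=0, dtype=np.float64
    )
    gy = y @ g.astype(np.float64)
    ym = y.mean()
    sxx = s2 - s1**2 / n
    sxy = gy - s1 * ym
    syy = float(np.sum(y**2) - n * ym**2)
    if np.any(sxx <= 0):
        raise DomainError("monomorphic SNP in simulated sample; enlarge n or eaf range")
    beta = sxy / sxx
    sigma2 = (syy - beta * sxy) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _per_snp_logistic(
    n_counts: np.ndarray, case_counts: np.ndarray, max_iter: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP univariate logistic MLE from genotype-grouped counts.

    ``n_counts`` and ``case_counts`` are (S, 3) arrays over dosage groups
    {0, 1, 2}.  Newton-Raphson on the grouped likelihood is exact for a
    3-cell predictor and vectorizes across SNPs.
    """
    n = n_counts.astype(np.float64)
    y = case_counts.astype(np.float64)
    gvals = np.array([0.0, 1.0, 2.0])
    tot = n.sum(axis=1)
    cases = y.sum(axis=1)
    if np.any(cases == 0) or np.any(cases == tot):
        raise DomainError("single-class outcome in simulated sample")
    a = np.log(cases / (tot - cases))
    b = np.zeros_like(a)
    h00 = h01 = h11 = det = None
    for _ in range(max_iter):
        mu = expit(a[:, None] + b[:, None] * gvals)
        w = n * mu * (1.0 - mu)
        resid = y - n * mu
        s0 = resid.sum(axis=1)
        s1 = (resid * gvals).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * gvals).sum(axis=1)
        h11 = (w * gvals**2).sum(axis=1)
        det = h00 * h11 - h01**2
        da = (h11 * s0 - h01 * s1) / det
        db = (-h01 * s0 + h00 * s1) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < 1e-12:
            break
    se_b = np.sqrt(h00 / det)
    return b, se_b


def simulate_sumstats(
    config: SimConfig,
    n_exposure_study: int = 339_224,
    n_outcome_cases: int = 16_003,
    n_outcome_controls: int = 41_335,
    panel: Sequence[SnpRecord] | None = None,
) -> tuple[list[SnpRecord], list[OutcomeAssociation]]:
    """Independent exposure and outcome studies summarized per SNP.

    Returns the panel re-estimated inside the exposure study (marginal OLS of
    exposure on each dosage) and outcome associations estimated inside a
    case-control outcome study (marginal logistic log-ORs).  Default study
    sizes mirror the emulated discovery GWAS and outcome consortium; scale
    them down for repeated-seed experiments.
    """
    if panel is None:
        panel = simulate_panel(config)
    eaf = np.array([r.eaf for r in panel])
    betas = np.array([r.beta_exposure for r in panel])
    noise_sd = _noise_sd(config, betas, eaf)

    # --- exposure study: continuous trait, per-SNP OLS ---
    rng_e = _rng(config.seed, _EXPO_STUDY)
    g_e = _draw_genotypes(rng_e, eaf, n_exposure_study, config.hard_calls)
    conf_e = rng_e.standard_normal(n_exposure_study)
    bmi_e = (
        config.bmi_mean
        + g_e.astype(np.float64) @ betas
        - float(np.sum(betas * 2.0 * eaf))
        + config.confounder_bmi * conf_e
        + noise_sd * rng_e.standard_normal(n_exposure_study)
    )
    beta_hat, se_hat = _per_snp_ols(g_e, bmi_e)
    eaf_e = g_e.mean(axis=0, dtype=np.float64) / 2.0
    p_hat = np.clip(2.0 * stats.norm.sf(np.abs(beta_hat) / se_hat), 1e-300, 1.0)
    exposure_records = [
        SnpRecord(
            rsid=r.rsid,
            chrom=r.chrom,
            pos=r.pos,
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            eaf=float(eaf_e[i]),
            beta_exposure=float(beta_hat[i]),
            se_exposure=float(se_hat[i]),
            p_exposure=float(p_hat[i]),
        )
        for i, r in enumerate(panel)
    ]

    # --- outcome study: case-control, per-SNP logistic ---
    n_out = n_outcome_cases + n_outcome_controls
    rng_o = _rng(config.seed, _OUT_STUDY)
    pleio = config.pleiotropy_mean + config.pleiotropy_sd * rng_o.standard_normal(len(panel))
    g_o = _draw_genotypes(rng_o, eaf, n_out, config.hard_calls)
    conf_o = rng_o.standard_normal(n_out)
    bmi_o = (
        config.bmi_mean
        + g_o.astype(np.float64) @ betas
        - float(np.sum(betas * 2.0 * eaf))
        + config.confounder_bmi * conf_o
        + noise_sd * rng_o.standard_normal(n_out)
    )
    linear = (
        config.theta * bmi_o
        + config.confounder_outcome * conf_o
        + g_o.astype(np.float64) @ pleio
    )
    alpha = _solve_intercept(linear, n_outcome_cases / n_out)
    case = rng_o.random(n_out) < expit(alpha + linear)

    g_hard = np.rint(np.asarray(g_o)).astype(np.int8)
    n_counts = np.empty((len(panel), 3), dtype=np.int64)
    c_counts = np.empty((len(panel), 3), dtype=np.int64)
    for gval in (0, 1, 2):
        mask = g_hard == gval
        n_counts[:, gval] = mask.sum(axis=0)
        c_counts[:, gval] = mask[case].sum(axis=0)
    byg, syg = _per_snp_logistic(n_counts, c_counts)
    eaf_o = g_o.mean(axis=0, dtype=np.float64) / 2.0
    p_o = np.clip(2.0 * stats.norm.sf(np.abs(byg) / syg), 1e-300, 1.0)
    outcome_records = [
        OutcomeAssociation(
            rsid=r.rsid,
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            eaf=float(eaf_o[i]),
            beta_outcome=float(byg[i]),
            se_outcome=float(syg[i]),
            p_outcome=float(p_o[i]),
        )
        for i, r in enumerate(panel)
    ]
    return exposure_records, outcome_records


def realized_parameters(config: SimConfig, panel: Sequence[SnpRecord]) -> dict:
    """Generative quantities implied by a drawn panel (for run manifests)."""
    eaf = np.array([r.eaf for r in panel])
    betas = np.array([r.beta_exposure for r in panel])
    var_score = float(np.sum(betas**2 * 2.0 * eaf * (1.0 - eaf)))
    out = asdict(config)
    out["realized_score_variance"] = var_score
    out["realized_r2"] = var_score / config.bmi_sd**2
    return out
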