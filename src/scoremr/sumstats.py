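"""Reading, validation, harmonization and conversion of GWAS summary statistics.

Instrument panels (per-allele SNP effects on the exposure, e.g. BMI) and
outcome association sets (per-allele log odds ratios for disease) share one
tab-separated dialect with required columns
``{rsid, effect_allele, other_allele, eaf, beta, se, p}`` and optional
``{chrom, pos, n}``.  Column names in a file can be remapped through a
dialect dictionary, so files from different consortia can be ingested
without rewriting headers.

Harmonization aligns outcome records to the panel's effect alleles:
allele-swapped records have their log-OR negated and frequency reflected,
strand flips are resolved by base complement, and palindromic (A/T, G/C)
variants are handled by a configurable policy because strand cannot be
inferred from the alleles alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DomainError, ParseError

__all__ = [
    "SnpRecord",
    "OutcomeAssociation",
    "HarmonizedPair",
    "HarmonizeReport",
    "read_panel",
    "write_panel",
    "read_outcome",
    "write_outcome",
    "harmonize",
    "or_ci_to_log",
    "log_to_or_ci",
    "load_published_snp_associations",
]

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical -> canonical identity dialect; callers remap file columns here
PANEL_REQUIRED = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "p")
PANEL_OPTIONAL = ("chrom", "pos", "n")

# harmonization actions
UNCHANGED = "unchanged"
SIGN_FLIPPED = "sign_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class SnpRecord:
    """One instrument SNP with its per-allele effect on the exposure."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_exposure: float
    se_exposure: float
    p_exposure: float = 1.0
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ParseError(f"{self.rsid}: effect and other allele identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise ParseError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not self.se_exposure > 0:
            raise ParseError(f"{self.rsid}: se must be positive, got {self.se_exposure}")
        if not 0.0 < self.p_exposure <= 1.0:
            raise ParseError(f"{self.rsid}: p {self.p_exposure} outside (0, 1]")


@dataclass(frozen=True)
class OutcomeAssociation:
    """Per-SNP outcome association on the log odds-ratio scale."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ParseError(f"{self.rsid}: effect and other allele identical")
        if not 0.0 <= self.eaf <= 1.0:
            raise ParseError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not self.se_outcome > 0:
            raise ParseError(f"{self.rsid}: se must be positive, got {self.se_outcome}")
        if not math.isfinite(math.exp(self.beta_outcome)):
            raise ParseError(f"{self.rsid}: beta_outcome {self.beta_outcome} overflows OR")


@dataclass(frozen=True)
class HarmonizedPair:
    """An instrument SNP matched to its (possibly reoriented) outcome record."""

    snp: SnpRecord
    outcome: OutcomeAssociation
    action: str

    @property
    def kept(self) -> bool:
        return self.action in (UNCHANGED, SIGN_FLIPPED)


@dataclass
class HarmonizeReport:
    """Result of aligning an outcome set to an instrument panel."""

    pairs: list[HarmonizedPair] = field(default_factory=list)
    unmatched_panel: list[str] = field(default_factory=list)
    unmatched_outcome: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.kept]

    @property
    def dropped(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if not p.kept]


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = {c: c for c in PANEL_REQUIRED + PANEL_OPTIONAL}
    if dialect:
        d.update(dialect)
    return d


def _read_table(path: str | Path, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [d[c] for c in PANEL_REQUIRED if d[c] not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    rename = {d[c]: c for c in PANEL_REQUIRED + PANEL_OPTIONAL if d[c] in df.columns}
    return df.rename(columns=rename)


def _row_float(row: pd.Series, col: str, line: int) -> float:
    raw = row[col]
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        rsid = row.get("rsid", "?")
        raise ParseError(f"line {line}, {rsid}: malformed {col} value {raw!r}") from exc


def read_panel(path: str | Path, dialect: Mapping[str, str] | None = None) -> list[SnpRecord]:
    """Read an instrument panel; one :class:`SnpRecord` per data row, order kept."""
    df = _read_table(path, dialect)
    records: list[SnpRecord] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2  # header is line 1
        rsid = str(row["rsid"])
        if rsid in seen:
            raise ParseError(f"line {line}: duplicate rsid {rsid}")
        seen.add(rsid)
        records.append(
            SnpRecord(
                rsid=rsid,
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=_row_float(row, "eaf", line),
                beta_exposure=_row_float(row, "beta", line),
                se_exposure=_row_float(row, "se", line),
                p_exposure=_row_float(row, "p", line),
                chrom=str(row["chrom"]) if "chrom" in row and pd.notna(row["chrom"]) else None,
                pos=int(float(row["pos"])) if "pos" in row and pd.notna(row["pos"]) else None,
            )
        )
    return records


def write_panel(records: Sequence[SnpRecord], path: str | Path) -> None:
    """Write records in the canonical tab-separated dialect (full float precision)."""
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [repr(r.eaf) for r in records],
            "beta": [repr(r.beta_exposure) for r in records],
            "se": [repr(r.se_exposure) for r in records],
            "p": [repr(r.p_exposure) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_outcome(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[OutcomeAssociation]:
    """Read outcome summary statistics (log-OR scale) in the shared dialect."""
    df = _read_table(path, dialect)
    records: list[OutcomeAssociation] = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2
        rsid = str(row["rsid"])
        if rsid in seen:
            raise ParseError(f"line {line}: duplicate rsid {rsid}")
        seen.add(rsid)
        records.append(
            OutcomeAssociation(
                rsid=rsid,
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=_row_float(row, "eaf", line),
                beta_outcome=_row_float(row, "beta", line),
                se_outcome=_row_float(row, "se", line),
                p_outcome=_row_float(row, "p", line),
            )
        )
    return records


def write_outcome(records: Sequence[OutcomeAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [repr(r.eaf) for r in records],
            "beta": [repr(r.beta_outcome) for r in records],
            "se": [repr(r.se_outcome) for r in records],
            "p": [repr(r.p_outcome) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT.get(a) == b


def _flip(outcome: OutcomeAssociation) -> OutcomeAssociation:
    """Reorient an outcome record to the opposite effect allele."""
    return replace(
        outcome,
        effect_allele=outcome.other_allele,
        other_allele=outcome.effect_allele,
        beta_outcome=-outcome.beta_outcome,
        eaf=1.0 - outcome.eaf,
    )


def _complement_record(outcome: OutcomeAssociation) -> OutcomeAssociation:
    return replace(
        outcome,
        effect_allele=COMPLEMENT.get(outcome.effect_allele, outcome.effect_allele),
        other_allele=COMPLEMENT.get(outcome.other_allele, outcome.other_allele),
    )


def harmonize(
    panel: Sequence[SnpRecord],
    outcome: Iterable[OutcomeAssociation],
    palindromic_policy: str = "drop",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizeReport:
    """Align outcome records to the panel's effect alleles.

    Policies for palindromic (A/T or G/C) variants:

    ``drop``
        drop when either frequency falls inside ``eaf_window`` (strand is then
        uninformative); otherwise orient by matching minor/major side.
    ``drop-all``
        drop every palindromic variant.
    ``ignore``
        trust the allele labels literally (same-strand files).
    """
    if palindromic_policy not in ("drop", "drop-all", "ignore"):
        raise ConfigError(f"unknown palindromic_policy {palindromic_policy!r}")
    by_rsid = {o.rsid: o for o in outcome}
    report = HarmonizeReport()
    matched: set[str] = set()
    for snp in panel:
        o = by_rsid.get(snp.rsid)
        if o is None:
            report.unmatched_panel.append(snp.rsid)
            continue
        matched.add(snp.rsid)
        report.pairs.append(_harmonize_one(snp, o, palindromic_policy, eaf_window))
    report.unmatched_outcome = [r for r in by_rsid if r not in matched]
    if report.unmatched_panel:
        logger.warning(
            "%d panel SNP(s) absent from the outcome set: %s",
            len(report.unmatched_panel),
            ", ".join(report.unmatched_panel[:10]),
        )
    return report


def _harmonize_one(
    snp: SnpRecord,
    o: OutcomeAssociation,
    policy: str,
    eaf_window: tuple[float, float],
) -> HarmonizedPair:
    panel_alleles = (snp.effect_allele, snp.other_allele)
    if _is_palindromic(*panel_alleles) and policy != "ignore":
        if policy == "drop-all":
            return HarmonizedPair(snp, o, DROPPED_PALINDROMIC)
        lo, hi = eaf_window
        if lo <= snp.eaf <= hi or lo <= o.eaf <= hi:
            return HarmonizedPair(snp, o, DROPPED_PALINDROMIC)
        # orient by frequency: effect alleles should sit on the same side of 0.5
        if {o.effect_allele, o.other_allele} != set(panel_alleles):
            return HarmonizedPair(snp, o, DROPPED_MISMATCH)
        if (snp.eaf < 0.5) == (o.eaf < 0.5):
            aligned = o if o.effect_allele == snp.effect_allele else replace(
                o, effect_allele=snp.effect_allele, other_allele=snp.other_allele
            )
            return HarmonizedPair(snp, aligned, UNCHANGED)
        flipped = _flip(o)
        aligned = replace(
            flipped, effect_allele=snp.effect_allele, other_allele=snp.other_allele
        )
        return HarmonizedPair(snp, aligned, SIGN_FLIPPED)

    # forward-strand match first, then complement (strand flip) before giving up
    for cand in (o, _complement_record(o)):
        if (cand.effect_allele, cand.other_allele) == panel_alleles:
            return HarmonizedPair(snp, cand, UNCHANGED)
        if (cand.other_allele, cand.effect_allele) == panel_alleles:
            return HarmonizedPair(snp, _flip(cand), SIGN_FLIPPED)
    logger.warning("%s: outcome alleles %s/%s incompatible with panel %s/%s",
                   snp.rsid, o.effect_allele, o.other_allele, *panel_alleles)
    return HarmonizedPair(snp, o, DROPPED_MISMATCH)


def or_ci_to_log(
    or_value: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert a printed ``OR (CI)`` row to a log-scale estimate and SE.

    ``beta = ln(OR)``; ``se = (ln(hi) - ln(lo)) / (2 z)`` with ``z`` the
    two-sided normal quantile of ``level`` (1.959964 at 95%).
    """
    if min(or_value, ci_low, ci_high) <= 0:
        raise DomainError("odds ratios and CI bounds must be positive")
    if not ci_low <= or_value <= ci_high:
        raise DomainError(f"CI ({ci_low}, {ci_high}) does not bracket OR {or_value}")
    if not 0.0 < level < 1.0:
        raise DomainError(f"confidence level {level} outside (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return beta, se


def log_to_or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Inverse of :func:`or_ci_to_log`: expand (beta, se) to ``(OR, lo, hi)``."""
    if se < 0:
        raise DomainError("se must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def load_published_snp_associations() -> pd.DataFrame:
    """Published per-SNP breast-cancer odds ratios for BMI-associated variants.

    The bundled table carries the 17 variants reported as associated at
    p < 0.05 after combining the two consortia (BCAC individual-level
    results and GAME-ON DRIVE summary results), with each consortium's
    OR (95% CI), effect-allele frequency, and the printed combined OR.
    """
    path = Path(__file__).parent / "data" / "consortium_per_snp_or.tsv"
    return pd.read_csv(path, sep="\t")
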