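"""End-to-end orchestration from a single YAML config, with a run manifest.

A run directory is write-once: each stage reads the outputs of earlier stages
(or user-supplied input files), writes its own TSV/JSON outputs, and the run
ends with ``manifest.json`` recording the config hash, seed, stage list and
SHA-256 digests of every input and output, so identical configs can be
verified to reproduce identical results byte for byte.

Stages (executed in dependency order, each optional):

``simulate``  panel + cohort (+ two-sample summary stats) from the generator
``score``     raw genetic score, control-only calibration to exposure units
``onesample`` adjusted logistic fit, per-study meta-analysis, strata
``twosample`` harmonization, per-SNP Wald ratios, IVW and Egger summaries
``meta``      row-wise cross-consortium combination of two per-SNP tables
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .meta import combine_consortia
from .onesample import (
    BASIC_COVARIATES,
    EXTENDED_COVARIATES,
    estimates_to_frame,
    fit_score_outcome,
    per_study_meta,
    stratified_fit,
)
from .score import calibrate_score, compute_gs, variance_explained
from .simulate import CohortTable, SimConfig, realized_parameters, simulate_cohort, simulate_panel, simulate_sumstats
from .sumstats import (
    harmonize,
    or_ci_to_log,
    read_outcome,
    read_panel,
    write_outcome,
    write_panel,
)
from .twosample import egger_regression, funnel_data, ivw_combine, wald_ratio

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "score", "onesample", "twosample", "meta")


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    stages: list[str] = field(default_factory=list)
    input_digests: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError("pipeline config must be a mapping")
    return loaded


def _validate_config(cfg: dict) -> None:
    stages = cfg.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config needs a non-empty 'stages' mapping")
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    for path in cfg.get("inputs", {}).values():
        if not Path(path).exists():
            raise ConfigError(f"input file does not exist: {path}")


def _covariate_profile(spec) -> list[str]:
    if spec in (None, "basic"):
        return list(BASIC_COVARIATES)
    if spec == "extended":
        return list(EXTENDED_COVARIATES)
    if isinstance(spec, list):
        return spec
    raise ConfigError(f"covariates must be 'basic', 'extended' or a list, got {spec!r}")


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Execute the configured stages and write outputs plus ``manifest.json``."""
    cfg = _load_config(config)
    _validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "scoremr_run"))
    if (out / "manifest.json").exists():
        raise ConfigError(f"{out} already holds a completed run (write-once)")
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else cfg.get("seed", 0)

    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical).hexdigest(),
        seed=seed,
        started=time.time(),
    )
    inputs = {k: Path(v) for k, v in cfg.get("inputs", {}).items()}
    for name, path in inputs.items():
        manifest.input_digests[name] = _sha256(path)

    artifacts: dict[str, Path] = dict(inputs)
    for stage in STAGE_ORDER:
        if stage not in cfg["stages"]:
            continue
        params = dict(cfg["stages"][stage] or {})  # copy: stages must not mutate config
        logger.info("running stage %s", stage)
        runner = _STAGES[stage]
        produced = runner(params, artifacts, out, seed)
        manifest.stages.append(stage)
        for path in produced:
            manifest.output_digests[str(path.relative_to(out))] = _sha256(path)
            artifacts[path.stem] = path

    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest


def _need(artifacts: dict[str, Path], key: str, stage: str) -> Path:
    if key not in artifacts:
        raise ConfigError(
            f"stage {stage!r} needs {key!r}; provide inputs.{key} or run the producing stage"
        )
    return artifacts[key]


def _stage_simulate(params: dict, artifacts, out: Path, seed: int) -> list[Path]:
    two_sample = params.pop("two_sample", None)
    config = SimConfig(seed=seed, **params)
    panel = simulate_panel(config)
    produced = []
    panel_path = out / "panel.tsv"
    write_panel(panel, panel_path)
    produced.append(panel_path)

    cohort = simulate_cohort(config, panel)
    cohort.dosages.to_csv(out / "dosages.tsv", sep="\t", index_label="individual_id")
    cohort.pheno.to_csv(out / "pheno.tsv", sep="\t", index_label="individual_id")
    produced += [out / "dosages.tsv", out / "pheno.tsv"]

    if two_sample:
        exposure, outcome = simulate_sumstats(config, panel=panel, **two_sample)
        write_panel(exposure, out / "exposure_panel.tsv")
        write_outcome(outcome, out / "outcome.tsv")
        produced += [out / "exposure_panel.tsv", out / "outcome.tsv"]

    (out / "sim_params.json").write_text(
        json.dumps(realized_parameters(config, panel), indent=2, sort_keys=True, default=str)
    )
    produced.append(out / "sim_params.json")
    return produced


def _stage_score(params: dict, artifacts, out: Path, seed: int) -> list[Path]:
    panel = read_panel(_need(artifacts, "panel", "score"))
    cohort = CohortTable(
        dosages=pd.read_csv(_need(artifacts, "dosages", "score"), sep="\t", index_col="individual_id"),
        pheno=pd.read_csv(_need(artifacts, "pheno", "score"), sep="\t", index_col="individual_id"),
    )
    gs = compute_gs(
        cohort.dosages,
        panel,
        weighted=params.get("weighted", True),
        missing_policy=params.get("missing_policy", "impute_eaf"),
    )
    controls = (cohort.pheno["case_status"] == 0) & cohort.pheno["bmi"].notna()
    calib = calibrate_score(gs[controls], cohort.pheno.loc[controls, "bmi"])
    scores = pd.DataFrame(
        {"gs_raw": gs, "score_calibrated": calib.apply(gs)}, index=gs.index
    )
    scores.to_csv(out / "scores.tsv", sep="\t", index_label="individual_id")
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "beta0": calib.beta0,
                "beta1": calib.beta1,
                "n_controls": calib.n,
                "r2_controls": variance_explained(
                    gs[controls], cohort.pheno.loc[controls, "bmi"]
                ),
                "weighted": params.get("weighted", True),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return [out / "scores.tsv", out / "calibration.json"]


def _stage_onesample(params: dict, artifacts, out: Path, seed: int) -> list[Path]:
    pheno = pd.read_csv(_need(artifacts, "pheno", "onesample"), sep="\t", index_col="individual_id")
    scores = pd.read_csv(_need(artifacts, "scores", "onesample"), sep="\t", index_col="individual_id")
    score = scores["score_calibrated"]
    covariates = _covariate_profile(params.get("covariates"))
    profile = params.get("covariates", "basic")
    per = float(params.get("per", 5.0))

    frames = []
    overall = fit_score_outcome(pheno, score, covariates, per=per, label="all")
    frames.append(estimates_to_frame([overall], model_profile=str(profile)))

    study = per_study_meta(pheno, score, covariates, study_var=params.get("study_var", "study"), per=per)
    per_study = estimates_to_frame(list(study.estimates.values()), model_profile=str(profile))
    per_study["label"] = "study:" + per_study["label"]
    frames.append(per_study)
    s = study.summary
    frames.append(
        pd.DataFrame(
            [
                {
                    "label": "META_FIXED",
                    "n": overall.n,
                    "beta": s.beta,
                    "se": s.se,
                    "or_per": math.exp(per * s.beta),
                    "ci_low": math.exp(per * s.ci_low),
                    "ci_high": math.exp(per * s.ci_high),
                    "p": s.p,
                    "per": per,
                    "model_profile": f"heterogeneity_p={s.q_p:.4g}",
                }
            ]
        )
    )

    for stratum in params.get("strata", []):
        res = stratified_fit(pheno, score, covariates, stratum, per=per)
        strat = estimates_to_frame(list(res.estimates.values()), model_profile=str(profile))
        strat["label"] = f"{stratum}:" + strat["label"]
        if res.het_p is not None:
            strat["model_profile"] = f"heterogeneity_p={res.het_p:.4g}"
        frames.append(strat)

    if params.get("categorical", False):
        cats = fit_score_outcome(
            pheno, score, covariates, form="categorical",
            cutpoints=tuple(params.get("cutpoints", (25.5, 26.0, 26.5))),
        )
        cat = estimates_to_frame(cats, model_profile=str(profile))
        cat["label"] = "group:" + cat["label"]
        frames.append(cat)

    pd.concat(frames, ignore_index=True).to_csv(out / "onesample.tsv", sep="\t", index=False)
    return [out / "onesample.tsv"]


def _stage_twosample(params: dict, artifacts, out: Path, seed: int) -> list[Path]:
    panel_key = "exposure_panel" if "exposure_panel" in artifacts else "panel"
    panel = read_panel(_need(artifacts, panel_key, "twosample"))
    outcome = read_outcome(_need(artifacts, "outcome", "twosample"))
    report = harmonize(
        panel,
        outcome,
        palindromic_policy=params.get("palindromic", "drop"),
    )
    se_mode = params.get("se_mode", "delta")
    per = float(params.get("per", 5.0))
    estimates = [wald_ratio(p, se_mode=se_mode) for p in report.kept]
    rows = funnel_data(estimates)
    rows.insert(1, "tag", "WALD")
    rows["se_causal"] = 1.0 / rows["precision"]
    rows["or_per"] = np.exp(per * rows["beta_causal"])

    ivw = ivw_combine(estimates)
    egger = egger_regression(report.kept)
    summary = pd.DataFrame(
        [
            {
                "rsid": "",
                "tag": "IVW",
                "beta_causal": ivw.beta,
                "precision": 1.0 / ivw.se,
                "se_causal": ivw.se,
                "or_per": math.exp(per * ivw.beta),
                "p": ivw.p,
                "q_p": ivw.q_p,
            },
            {
                "rsid": "",
                "tag": "EGGER",
                "beta_causal": egger.slope,
                "precision": 1.0 / egger.se_slope,
                "se_causal": egger.se_slope,
                "or_per": math.exp(per * egger.slope),
                "p": egger.p_slope,
                "intercept": egger.intercept,
                "intercept_p": egger.p_intercept,
            },
        ]
    )
    result = pd.concat([rows, summary], ignore_index=True)
    result.to_csv(out / "twosample.tsv", sep="\t", index=False)

    dropped = pd.DataFrame(
        {
            "rsid": [p.snp.rsid for p in report.dropped],
            "action": [p.action for p in report.dropped],
        }
    )
    dropped.to_csv(out / "twosample_dropped.tsv", sep="\t", index=False)
    return [out / "twosample.tsv", out / "twosample_dropped.tsv"]


def _read_per_snp_estimates(path: Path) -> pd.DataFrame:
    """Accept either (rsid, beta, se) or printed-style (rsid, or, ci_low, ci_high)."""
    df = pd.read_csv(path, sep="\t")
    if {"beta", "se"} <= set(df.columns):
        return df[["rsid", "beta", "se"]]
    if {"or", "ci_low", "ci_high"} <= set(df.columns):
        conv = [or_ci_to_log(o, lo, hi) for o, lo, hi in df[["or", "ci_low", "ci_high"]].itertuples(index=False)]
        return pd.DataFrame(
            {"rsid": df["rsid"], "beta": [b for b, _ in conv], "se": [s for _, s in conv]}
        )
    raise ConfigError(f"{path}: need columns (rsid, beta, se) or (rsid, or, ci_low, ci_high)")


def _stage_meta(params: dict, artifacts, out: Path, seed: int) -> list[Path]:
    a = _read_per_snp_estimates(Path(params.get("source_a") or _need(artifacts, "source_a", "meta")))
    b = _read_per_snp_estimates(Path(params.get("source_b") or _need(artifacts, "source_b", "meta")))
    combined = combine_consortia(a, b)
    combined.to_csv(out / "combined.tsv", sep="\t", index=False)
    return [out / "combined.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "onesample": _stage_onesample,
    "twosample": _stage_twosample,
    "meta": _stage_meta,
}
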