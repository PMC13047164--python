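"""End-to-end orchestration: ingest or simulate, impute, assess, summarize,
stratified rank tests, correlation matrix, report files and run manifest.

Outputs (CSV, written to the configured directory):

* ``samples.csv``                — the ingested or simulated study
* ``concentration_summary.csv``  — per-analyte detection rates and medians
* ``risk_by_age_gender.csv``     — CR (×10⁻⁶) and HQ (×10⁻²) medians and
  IQRs per analyte per age group × gender, with per-stratum totals rows
* ``stratified_risk_tests.csv``  — rank-test battery over the stratifications
* ``correlation_matrix.csv``     — Spearman matrix of DBPs and WQPs with
  significance stars
* ``manifest.json``              — config echo, seed, versions, row counts
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .core_data import (
    Analyte,
    CsvDialect,
    Season,
    Source,
    Stage,
    ValidationError,
    builtin_registry,
    impute_censored,
    read_samples,
    samples_to_frame,
    summarize_concentrations,
    summary_to_frame,
    write_samples,
)
from .nonparam_stats import jonckheere_terpstra, kruskal_wallis_h, mann_whitney_z, spearman_matrix
from .risk_model import (
    AgeGroup,
    Gender,
    assess,
    builtin_exposure_groups,
    format_risk_report,
    summarize_risks,
)
from .synthetic_data import default_calibration, default_design, generate

log = logging.getLogger("dbprisk")

STRATIFICATIONS = ("age_gender", "season", "stage", "source", "disinfectant")

__all__ = ["PipelineConfig", "validate", "run", "STRATIFICATIONS"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``mode`` is ``"simulate"`` (requires ``seed``) or ``"csv"`` (requires
    ``input_path``).  ``stratifications`` selects which stratified analyses
    to run, from :data:`STRATIFICATIONS`.
    """

    mode: str = "simulate"
    input_path: str | None = None
    seed: int | None = None
    imputation_rule: str = "half_lod"
    stratifications: Sequence[str] = field(default_factory=lambda: list(STRATIFICATIONS))
    outdir: str = "dbprisk_out"
    nd_token: str = "ND"
    unit: str = "mg_per_L"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "input_path": self.input_path,
            "seed": self.seed,
            "imputation_rule": self.imputation_rule,
            "stratifications": list(self.stratifications),
            "outdir": str(self.outdir),
            "nd_token": self.nd_token,
            "unit": self.unit,
        }


def validate(config: PipelineConfig) -> list[str]:
    """Schema-check a config (and input CSV header, if any) without running.
    Returns a list of actionable findings; empty means valid."""
    findings: list[str] = []
    if config.mode not in ("simulate", "csv"):
        findings.append(f"mode: expected 'simulate' or 'csv', got {config.mode!r}")
    if config.mode == "simulate" and config.seed is None:
        findings.append("seed: required in simulate mode")
    if config.mode == "csv":
        if not config.input_path:
            findings.append("input_path: required in csv mode")
        elif not Path(config.input_path).exists():
            findings.append(f"input_path: file not found: {config.input_path}")
        else:
            header = pd.read_csv(config.input_path, nrows=0).columns
            needed = ["sample_id", "waterworks_id", "season", "stage", "source", "disinfectant"]
            needed += [a.value for a in Analyte] + ["ph", "pi", "fc"]
            for col in needed:
                if col not in header:
                    findings.append(f"input_path: missing column {col!r}")
    if config.imputation_rule != "half_lod":
        findings.append(f"imputation_rule: unknown rule {config.imputation_rule!r}")
    for s in config.stratifications:
        if s not in STRATIFICATIONS:
            findings.append(f"stratifications: unknown name {s!r}; expected one of {STRATIFICATIONS}")
    if config.unit not in ("mg_per_L", "ug_per_L"):
        findings.append(f"unit: expected 'mg_per_L' or 'ug_per_L', got {config.unit!r}")
    return findings


def _stage_timer(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _test_row(result, stratification: str, analyte: str, comparison: str) -> dict:
    return {
        "test": result.test.value,
        "stratification": stratification,
        "analyte": analyte,
        "comparison": comparison,
        "statistic": round(result.statistic, 3),
        "p": result.p,
        "group_sizes": "/".join(str(s) for s in result.group_sizes),
        "ties_present": result.ties_present,
    }


def stratified_tests(records: pd.DataFrame, stratifications: Sequence[str]) -> pd.DataFrame:
    """Rank-test battery over the requested stratifications.

    Sample-level contrasts (season, stage, source, disinfectant) use the
    per-sample carcinogenic risks of the gender-combined 6–8 group, the
    most exposed stratum; risk is a positive multiple of concentration
    within a fixed exposure group, so every rank statistic is identical to
    the one computed on concentrations.  The age contrast uses the
    gender-combined records of all four groups ordered young to old; gender
    contrasts compare male against female within each age group (male
    first; these derive from the same water samples with different
    exposure constants, so they are paired vectors compared with a
    two-sample procedure).
    """
    rows = []
    base = records[(records["age_group"] == AgeGroup.A6_8.value) & (records["gender"] == Gender.TOTAL.value)]
    for analyte, sub in base.groupby("analyte", sort=False, observed=True):
        cr = sub.set_index("sample_id")["cr"]
        by = {c: sub.set_index("sample_id")[c] for c in ("season", "stage", "source", "disinfectant")}
        if "season" in stratifications:
            res = mann_whitney_z(cr[by["season"] == Season.DRY.value], cr[by["season"] == Season.WET.value])
            rows.append(_test_row(res, "season", analyte, "dry_vs_wet"))
        if "stage" in stratifications:
            groups = [cr[by["stage"] == s.value] for s in (Stage.FINISHED, Stage.TERMINAL, Stage.SECONDARY)]
            if all(len(g) for g in groups):
                rows.append(_test_row(kruskal_wallis_h(groups), "stage", analyte, "finished/terminal/secondary"))
                rows.append(
                    _test_row(jonckheere_terpstra(groups), "stage", analyte, "trend finished->secondary")
                )
        if "source" in stratifications:
            surf = cr[by["source"] == Source.SURFACE.value]
            grnd = cr[by["source"] == Source.GROUND.value]
            if len(surf) and len(grnd):
                rows.append(_test_row(mann_whitney_z(surf, grnd), "source", analyte, "surface_vs_ground"))
        if "disinfectant" in stratifications:
            groups = [g["cr"].to_numpy() for _, g in sub.groupby("disinfectant", sort=True, observed=True)]
            if len(groups) >= 2:
                rows.append(_test_row(kruskal_wallis_h(groups), "disinfectant", analyte, "all_types"))
    if "age_gender" in stratifications:
        total = records[records["gender"] == Gender.TOTAL.value]
        for analyte, sub in total.groupby("analyte", sort=False, observed=True):
            groups = [
                sub[sub["age_group"] == a.value]["cr"].to_numpy()
                for a in (AgeGroup.A6_8, AgeGroup.A9_11, AgeGroup.A12_14, AgeGroup.A15_17)
            ]
            rows.append(_test_row(jonckheere_terpstra(groups), "age", analyte, "trend 6-8 -> 15-17"))
            rows.append(_test_row(kruskal_wallis_h(groups), "age", analyte, "four age groups"))
        for (analyte, age), sub in records.groupby(["analyte", "age_group"], sort=False, observed=True):
            male = sub[sub["gender"] == Gender.MALE.value]["cr"].to_numpy()
            female = sub[sub["gender"] == Gender.FEMALE.value]["cr"].to_numpy()
            rows.append(_test_row(mann_whitney_z(male, female), "gender", analyte, f"male_vs_female {age}"))
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the config; returns the manifest."""
    findings = validate(config)
    if findings:
        raise ValidationError("invalid config: " + "; ".join(findings))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = builtin_registry()
    dialect = CsvDialect(nd_token=config.nd_token, unit=config.unit)

    with _stage_timer("ingest"):
        if config.mode == "simulate":
            samples = generate(default_design(), default_calibration(), seed=config.seed)
        else:
            samples = read_samples(config.input_path, dialect)
        write_samples(samples, outdir / "samples.csv")

    with _stage_timer("impute"):
        imputed = impute_censored(samples, registry, rule=config.imputation_rule)

    with _stage_timer("summarize_concentrations"):
        summary_rows = []
        for a in Analyte:
            summary_rows.extend(summarize_concentrations(imputed, a))
        conc_summary = summary_to_frame(summary_rows)
        conc_summary.to_csv(outdir / "concentration_summary.csv", index=False)

    with _stage_timer("assess"):
        records = assess(imputed, registry, builtin_exposure_groups())

    with _stage_timer("summarize_risks"):
        summary = summarize_risks(records, ["age_group", "gender"])
        report = format_risk_report(summary, ["age_group", "gender"])
        report.to_csv(outdir / "risk_by_age_gender.csv", index=False)

    with _stage_timer("stratified_tests"):
        tests = stratified_tests(records, config.stratifications)
        tests.to_csv(outdir / "stratified_risk_tests.csv", index=False)

    with _stage_timer("correlation_matrix"):
        df = samples_to_frame(imputed)
        variables = df[[a.value for a in Analyte] + ["ph", "pi", "fc"]]
        matrix = spearman_matrix(variables)
        matrix.starred().to_csv(outdir / "correlation_matrix.csv")

    manifest = {
        "package": "dbprisk",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "library_versions": {
            "numpy": __import__("numpy").__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {
            "samples": len(samples),
            "concentration_summary": int(len(conc_summary)),
            "risk_by_age_gender": int(len(report)),
            "stratified_risk_tests": int(len(tests)),
            "risk_records": int(len(records)),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
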