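"""Config-driven orchestration of the comparative risk-classification
analysis.

Stage order mirrors the study flow: load or generate a cohort, apply
eligibility (age 30-75, no established CVD), inject/handle blood-pressure
missingness, multiply impute, score the requested models, average the
predicted probabilities over imputations (the default "mean of the imputed
data sets" mode; a per-dataset Rubin-pooled mode is also available for
scalar summaries), extrapolate the 5-year D:A:D risks to 10 years under a
constant hazard, categorize, and compare every model against the reference
(D:A:D 2010) with cross-tabulations and kappa statistics, plus cumulative
risk curves and age-subgroup summaries. Every stage is a pure function of
(input, config, seed); the manifest records enough to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementError,
    AgreementResult,
    CrossTab,
    cohen_kappa,
    cross_tabulate,
    cumulative_distribution,
    subgroup_summary,
)
from .cohort import CohortTable, ExclusionReport, apply_eligibility, read_cohort, write_cohort
from .imputation import ImputationSpec, impute
from .risk_models import (
    ModelID,
    extrapolate_probability,
    load_coefficients,
    score_frame,
)
from .synthetic import GeneratorConfig, generate, inject_missingness

__all__ = ["PipelineConfig", "RunReport", "ConfigError", "run_pipeline",
           "table3_from_categories"]

MODEL_ORDER = [m.value for m in ModelID]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    input: str | None = None                       # cohort CSV; None -> generator
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: list[str] = field(default_factory=lambda: list(MODEL_ORDER))
    reference_model: str = "DAD_2010"
    dad_horizon: int = 10                          # categorize D:A:D at 5 or 10 years
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    kappa_scheme: str = "unweighted"
    age_bins: list[tuple[float, float]] = field(
        default_factory=lambda: [(30, 39), (40, 49), (50, 59), (60, 75)])
    sensitivity: str = "all"                       # "all" | "validated_bp_only"
    pooling: str = "mean"                          # "mean" | "rubin"
    ascvd_race: str = "black"
    output_dir: str | None = None
    seed: int = 20141101

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_ORDER]
        if unknown:
            raise ConfigError(f"unknown models {unknown}")
        if self.reference_model not in self.models:
            raise ConfigError(
                f"reference model {self.reference_model!r} not among {self.models}")
        if self.dad_horizon not in (5, 10):
            raise ConfigError("dad_horizon must be 5 or 10")
        if self.sensitivity not in ("all", "validated_bp_only"):
            raise ConfigError(f"unknown sensitivity mode {self.sensitivity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "generator" in raw:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        if "imputation" in raw:
            raw["imputation"] = ImputationSpec(**raw["imputation"])
        if "age_bins" in raw:
            raw["age_bins"] = [tuple(b) for b in raw["age_bins"]]
        return cls(**raw)


@dataclass
class ModelSummary:
    model_id: str
    horizon_years: float
    median: float
    iqr: tuple[float, float]
    proportions: dict[str, float]      # percent per category
    n_age_out_of_range: int
    extrapolated: bool


@dataclass
class RunReport:
    exclusion: ExclusionReport
    probabilities: pd.DataFrame        # per participant x model (pooled)
    categories: pd.DataFrame
    summaries: dict[str, ModelSummary]
    panels: list[tuple[CrossTab, AgreementResult]]
    subgroup: pd.DataFrame
    manifest: dict
    log: list[str]


def _config_hash(config: PipelineConfig) -> str:
    # repr of the dataclass dict is deterministic (field order fixed) and
    # tolerates tuple-keyed sub-dicts that JSON cannot encode; the output
    # location is not part of the analysis identity
    d = dataclasses.asdict(config)
    d.pop("output_dir", None)
    blob = repr(d)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def table3_from_categories(
    categories: pd.DataFrame,
    reference: str,
    scheme: str = "unweighted",
) -> list[tuple[CrossTab, AgreementResult]]:
    """One (cross-tab, agreement) panel per non-reference model, reference on
    the rows, in canonical model order (independent of column order)."""
    if reference not in categories.columns:
        raise ConfigError(f"reference model {reference!r} missing from categories")
    panels = []
    others = [m for m in MODEL_ORDER if m in categories.columns and m != reference]
    for model in others:
        tab = cross_tabulate(categories[reference], categories[model],
                             row_model=reference, col_model=model)
        panels.append((tab, cohen_kappa(tab, scheme)))
    return panels


def run_pipeline(config: PipelineConfig) -> RunReport:
    log: list[str] = []
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    # --- cohort ------------------------------------------------------------
    if config.input:
        cohort, parse_report = read_cohort(config.input)
        log.append(f"read {len(cohort)} records from {config.input} "
                   f"({parse_report.total} cells coerced/defaulted)")
    else:
        gen = dataclasses.replace(config.generator, seed=int(seeds[0]))
        cohort = generate(gen)
        log.append(f"generated synthetic cohort n={len(cohort)}")

    cohort, exclusion = apply_eligibility(cohort)
    log.append(f"eligibility: kept {exclusion.kept}/{exclusion.total_in} "
               f"({exclusion.reasons})")

    if not config.input:
        mc = config.generator.missingness
        if mc.fraction > 0:
            cohort, _truth = inject_missingness(
                cohort, mc.fraction, mc.mechanism, seed=int(seeds[1]),
                beta_age=mc.beta_age, beta_female=mc.beta_female)
            log.append(f"injected {mc.mechanism} BP missingness at {mc.fraction:.1%}")

    # --- sensitivity subset / imputation -----------------------------------
    if config.sensitivity == "validated_bp_only":
        keep = cohort.frame["bp_device_validated"].astype(bool) & cohort.frame["sbp"].notna()
        cohort = CohortTable(cohort.frame[keep].reset_index(drop=True), cohort.provenance)
        datasets = [cohort]
        log.append(f"sensitivity subset: {len(cohort)} complete validated-device records; "
                   "imputation skipped")
    elif cohort.frame["sbp"].isna().any():
        spec = dataclasses.replace(config.imputation, seed=int(seeds[2]))
        datasets = impute(cohort, spec)
        log.append(f"imputed BP: m={spec.m} datasets, {spec.iterations} sweeps")
    else:
        datasets = [cohort]
        log.append("no missing BP; imputation skipped")

    # --- scoring ------------------------------------------------------------
    ids = datasets[0].frame["id"]
    probabilities = pd.DataFrame(index=ids)
    categories = pd.DataFrame(index=ids)
    summaries: dict[str, ModelSummary] = {}
    for model in [m for m in MODEL_ORDER if m in config.models]:
        coeffs = load_coefficients(model)
        per_ds = np.column_stack([
            score_frame(ds.frame, coeffs, default_race=config.ascvd_race)[
                "probability"].to_numpy()
            for ds in datasets
        ])
        pooled = per_ds.mean(axis=1)
        horizon = float(coeffs.horizon_years)
        extrapolated = False
        if coeffs.form == "rate" and config.dad_horizon == 10:
            pooled = np.asarray(extrapolate_probability(pooled, 5, 10))
            horizon, extrapolated = 10.0, True
        probabilities[model] = pooled
        cats = np.where(pooled < 0.10, "low",
                        np.where(pooled <= 0.20, "moderate", "high"))
        categories[model] = cats
        res = score_frame(datasets[0].frame, coeffs, default_race=config.ascvd_race)
        curve = cumulative_distribution(pooled, model)
        summaries[model] = ModelSummary(
            model_id=model,
            horizon_years=horizon,
            median=curve.median,
            iqr=curve.iqr,
            proportions={c: 100.0 * float((cats == c).mean())
                         for c in ("low", "moderate", "high")},
            n_age_out_of_range=int(res["age_out_of_range"].sum()),
            extrapolated=extrapolated,
        )
        log.append(f"scored {model}: median {curve.median:.3f}, "
                   f"{summaries[model].n_age_out_of_range} outside model age range")

    # --- agreement / subgroups ----------------------------------------------
    panels = table3_from_categories(categories, config.reference_model,
                                    config.kappa_scheme)
    age = datasets[0].frame.set_index("id")["age"]
    subgroup = subgroup_summary(age, categories, config.age_bins)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_scored": int(len(ids)),
        "models": [m for m in MODEL_ORDER if m in config.models],
        "reference_model": config.reference_model,
        "dad_horizon": config.dad_horizon,
        "kappa_scheme": config.kappa_scheme,
        "sensitivity": config.sensitivity,
    }
    report = RunReport(exclusion, probabilities, categories, summaries,
                       panels, subgroup, manifest, log)
    if config.output_dir:
        _write_outputs(report, Path(config.output_dir), config)
    return report


def format_panel_text(panels: list[tuple[CrossTab, AgreementResult]]) -> str:
    """Fixed-width text rendering of the agreement panels (reference model on
    the rows)."""
    lines = []
    for tab, res in panels:
        lines.append(f"{tab.row_model} vs {tab.col_model}")
        header = f"{'':>12}" + "".join(f"{lbl:>10}" for lbl in tab.labels) + f"{'total':>10}"
        lines.append(header)
        for i, lbl in enumerate(tab.labels):
            row = f"{lbl:>12}" + "".join(f"{int(c):>10}" for c in tab.counts[i])
            lines.append(row + f"{int(tab.row_margins[i]):>10}")
        lines.append(f"{'total':>12}" + "".join(f"{int(c):>10}" for c in tab.col_margins)
                     + f"{tab.total:>10}")
        lines.append(f"  agreement: {res.percent_agreement:.1f}%   "
                     f"kappa ({res.scheme}): {res.kappa:.2f} "
                     f"[{res.interpretation}]   p = {res.p:.2g}")
        lines.append("")
    return "\n".join(lines)


def _write_outputs(report: RunReport, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "exclusion_report.json").write_text(report.exclusion.to_json())
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2,
                                                     sort_keys=True))
    summaries = {
        m: {
            "horizon_years": s.horizon_years,
            "median": s.median,
            "iqr": list(s.iqr),
            "proportions_percent": s.proportions,
            "n_age_out_of_range": s.n_age_out_of_range,
            "extrapolated": s.extrapolated,
        }
        for m, s in report.summaries.items()
    }
    (outdir / "risk_summary.json").write_text(json.dumps(summaries, indent=2,
                                                         sort_keys=True))
    agreement = [
        {
            "row_model": tab.row_model,
            "col_model": tab.col_model,
            "counts": tab.counts.tolist(),
            "percent_agreement": round(res.percent_agreement, 1),
            "kappa": round(res.kappa, 2),
            "scheme": res.scheme,
            "se": res.se,
            "p": res.p,
            "interpretation": res.interpretation,
        }
        for tab, res in report.panels
    ]
    (outdir / "agreement.json").write_text(json.dumps(agreement, indent=2))
    (outdir / "agreement.txt").write_text(format_panel_text(report.panels))
    for model in report.probabilities.columns:
        curve = cumulative_distribution(report.probabilities[model], model)
        curve.to_frame().to_csv(outdir / f"cumulative_{model}.csv", index=False)
    report.subgroup.to_csv(outdir / "subgroup.csv", index=False)
    (outdir / "log.txt").write_text("\n".join(report.log) + "\n")
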