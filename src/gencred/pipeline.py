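"""End-to-end orchestration: catalog -> pooled results -> classified report.

Outputs written to the run directory:

* ``summary.tsv``         — one row per variant x genetic model (pooled OR,
  CI, p, Q, I^2 with CI, tau^2, method, power);
* ``classification.tsv``  — one row per variant (p-values, BFDP grid,
  Venice grades, Egger test, labels before/after validation);
* ``summary_formatted.tsv`` — human-readable per-variant rows in the
  classic field-synopsis table layout;
* ``funnel/*.tsv``        — per-variant funnel-plot data (allelic model);
* ``run_log.txt``         — config echo, row accounting and class counts.

All outputs are deterministic functions of the inputs and configuration.
"""

from __future__ import annotations

import math
import re
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import catalog_io
from .catalog_io import ExternalValidationRecord, StudyGenotypeRecord
from .credibility import (
    CredibilityConfig, CredibilityResult, assess_variant, statistical_power,
)
from .genetic_models import MODELS, contrast_table, effect_estimate
from .meta_analysis import MetaResult, meta_analyse
from .small_study_bias import EggerError, egger_test, funnel_data


@dataclass
class RunConfig:
    catalog_path: str = ""
    external_path: Optional[str] = None
    out_dir: str = "gencred_out"
    credibility: CredibilityConfig = field(default_factory=CredibilityConfig)
    min_maf: float = 0.01
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Build a config from a flat key: value file plus overrides."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        cred_fields = CredibilityConfig.__dataclass_fields__
        cred_kwargs = {}
        for key in list(raw):
            if key in cred_fields:
                value = raw.pop(key)
                if key == "prior_grid":
                    value = tuple(float(x) for x in value)
                cred_kwargs[key] = value
        return cls(credibility=CredibilityConfig(**cred_kwargs), **raw)


@dataclass
class VariantAnalysis:
    """Everything the pipeline computed for one variant."""

    model_results: dict[str, MetaResult]
    credibility: CredibilityResult
    funnel: pd.DataFrame


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    classification: pd.DataFrame
    analyses: dict[tuple[str, str], VariantAnalysis]
    parse_report: catalog_io.ParseReport
    out_dir: Optional[Path] = None


def analyse_variant(
    records: list[StudyGenotypeRecord],
    config: CredibilityConfig = CredibilityConfig(),
    external: Optional[ExternalValidationRecord] = None,
) -> VariantAnalysis:
    """Pool one variant under all three models and appraise credibility.

    The Egger test and funnel export run on the allelic-model per-study
    effects only.
    """
    model_results = {
        m: meta_analyse(records, m, min_studies=config.min_studies)
        for m in MODELS
    }
    allelic_effects = [
        effect_estimate(contrast_table(r, "allelic"), study_id=r.study_id)
        for r in records
    ]
    egger = None
    if len(allelic_effects) >= 3:
        try:
            egger = egger_test(allelic_effects, config.egger_threshold)
        except EggerError:
            egger = None
    cred = assess_variant(model_results, egger=egger, external=external,
                          config=config)
    return VariantAnalysis(model_results=model_results, credibility=cred,
                           funnel=funnel_data(allelic_effects))


def _model_power(result: MetaResult, alpha: float) -> float:
    if result.status != "ok":
        return float("nan")
    return statistical_power(result.log_or, result.se_log, alpha)


def summary_frame(analyses: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Machine-readable summary: one row per variant x model."""
    rows = []
    for (gene, variant_id), va in analyses.items():
        for model in MODELS:
            r = va.model_results[model]
            rows.append({
                "gene": gene, "variant_id": variant_id, "model": model,
                "status": r.status, "n_studies": r.n_studies,
                "n_cases": r.n_cases, "n_controls": r.n_controls,
                "or": r.pooled_or, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p": r.p_value, "q": r.q, "q_p": r.q_p,
                "i2": r.i2, "i2_low": r.i2_low, "i2_high": r.i2_high,
                "tau2": r.tau2, "method": r.method,
                "power": _model_power(r, alpha),
            })
    return pd.DataFrame(rows)


def classification_frame(analyses: dict,
                         config: CredibilityConfig) -> pd.DataFrame:
    """One row per variant: appraisal inputs, grades and labels."""
    rows = []
    for (gene, variant_id), va in analyses.items():
        cred = va.credibility
        row = {
            "gene": gene, "variant_id": variant_id,
            "p_allelic": cred.p_values.get("allelic", float("nan")),
            "p_recessive": cred.p_values.get("recessive", float("nan")),
            "p_dominant": cred.p_values.get("dominant", float("nan")),
            "headline_model": cred.headline_model or "",
            "power": cred.power.power if cred.power else float("nan"),
            "power_basis": cred.power.basis if cred.power else "",
            "i2_used": cred.i2_used,
            "venice_amount": cred.venice.amount if cred.venice else "",
            "venice_replication": cred.venice.replication if cred.venice else "",
            "egger_p": cred.egger.p_value if cred.egger else float("nan"),
            "egger_flagged": cred.egger.flagged if cred.egger else "",
            "classification": cred.label,
            "classification_after_validation": cred.label_after_validation,
            "validation_status": cred.validation_status,
        }
        for b in cred.bfdp_grid:
            row[f"bfdp_pi_{b.prior_pi:g}"] = b.bfdp
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "na"
    if p < 1e-3:
        return f"{p:.2E}"
    return f"{p:.3f}"


def render_summary(analyses: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Human-readable per-variant rows in field-synopsis table layout.

    Per model: N, OR (95% CI), p, I^2 (95% CI), heterogeneity p, power.
    Models that could not be pooled render as "na".
    """
    rows = []
    for (gene, variant_id), va in analyses.items():
        row = {"gene": gene, "variant": variant_id}
        any_r = next(iter(va.model_results.values()))
        row["samples"] = ""
        for model in MODELS:
            r = va.model_results[model]
            prefix = model
            if r.status != "ok":
                for col in ("n", "or_ci", "p", "i2_ci", "het_p", "power"):
                    row[f"{prefix}_{col}"] = "na"
                continue
            row[f"{prefix}_n"] = str(r.n_studies)
            row[f"{prefix}_or_ci"] = (
                f"{r.pooled_or:.2f} ({r.ci_low:.2f} to {r.ci_high:.2f})")
            row[f"{prefix}_p"] = _fmt_p(r.p_value)
            row[f"{prefix}_i2_ci"] = (
                f"{r.i2:.0f} ({r.i2_low:.0f} to {r.i2_high:.0f})")
            row[f"{prefix}_het_p"] = _fmt_p(r.q_p)
            row[f"{prefix}_power"] = f"{_model_power(r, alpha):.2f}"
            if r.n_cases:
                row["samples"] = f"{r.n_cases} vs {r.n_controls}"
        row["classification"] = va.credibility.label
        rows.append(row)
    columns = ["gene", "variant", "samples"]
    for model in MODELS:
        columns += [f"{model}_{c}"
                    for c in ("n", "or_ci", "p", "i2_ci", "het_p", "power")]
    columns.append("classification")
    return pd.DataFrame(rows, columns=columns)


def _safe_name(gene: str, variant_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", f"{gene}_{variant_id}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole analysis and write all artifacts to ``config.out_dir``.

    On any failure, partially written outputs are removed before the
    exception propagates.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline_inner(config, out_dir)
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run_pipeline_inner(config: RunConfig, out_dir: Path) -> PipelineResult:
    report = catalog_io.read_catalog(config.catalog_path)
    eligibility = catalog_io.apply_eligibility(report.records, config.min_maf)
    groups = catalog_io.group_by_variant(eligibility.kept)

    externals: dict[tuple[str, str], ExternalValidationRecord] = {}
    if config.external_path:
        ext_report = catalog_io.read_external_validation(config.external_path)
        externals = {r.variant.label: r for r in ext_report.records}

    analyses: dict[tuple[str, str], VariantAnalysis] = {}
    for label, records in groups.items():
        analyses[label] = analyse_variant(
            records, config.credibility, externals.get(label))

    alpha = config.credibility.alpha
    summary = summary_frame(analyses, alpha)
    classification = classification_frame(analyses, config.credibility)
    formatted = render_summary(analyses, alpha)

    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    classification.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    formatted.to_csv(out_dir / "summary_formatted.tsv", sep="\t", index=False)

    funnel_dir = out_dir / "funnel"
    funnel_dir.mkdir(exist_ok=True)
    for (gene, variant_id), va in analyses.items():
        va.funnel.to_csv(funnel_dir / f"{_safe_name(gene, variant_id)}.tsv",
                         sep="\t", index=False)

    class_counts = (classification["classification"].value_counts().to_dict()
                    if len(classification) else {})
    log_lines = ["# gencred run log", "", "## config"]
    cfg = asdict(config)
    cfg["credibility"] = asdict(config.credibility)
    log_lines.append(yaml.safe_dump(cfg, sort_keys=True).rstrip())
    log_lines += [
        "", "## input accounting",
        f"rows_read: {report.n_rows}",
        f"rows_kept: {len(report.records)}",
        f"rows_rejected: {len(report.rejects)}",
    ]
    for idx, reason in report.rejects:
        log_lines.append(f"rejected_row: {idx}\t{reason}")
    for rec, reason in eligibility.excluded:
        log_lines.append(
            f"excluded_study: {rec.study_id}\t{rec.variant.variant_id}\t{reason}")
    for (gene, vid), flag in eligibility.flags.items():
        log_lines.append(f"flagged_variant: {gene}\t{vid}\t{flag}")
    log_lines += ["", "## classification counts"]
    for name in sorted(class_counts):
        log_lines.append(f"{name}: {class_counts[name]}")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(summary=summary, classification=classification,
                          analyses=analyses, parse_report=report,
                          out_dir=out_dir)


def revalidate_classification(
    classification: pd.DataFrame,
    externals: dict[tuple[str, str], ExternalValidationRecord],
    config: CredibilityConfig = CredibilityConfig(),
) -> pd.DataFrame:
    """Re-apply external validation to an existing classification table."""
    from .credibility import apply_validation

    out = classification.copy()
    labels, statuses = [], []
    for _, row in out.iterrows():
        ext = externals.get((row["gene"], row["variant_id"]))
        label, status = apply_validation(row["classification"], ext, config)
        labels.append(label)
        statuses.append(status)
    out["classification_after_validation"] = labels
    out["validation_status"] = statuses
    return out
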