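"""End-to-end risk-adjustment pipeline: data -> flags -> outcomes -> models.

One call (or the ``casemix run`` command) takes a cohort — read from the
interchange CSVs or drawn from the synthetic generator — and produces the full
set of analysis artifacts: comorbidity prevalence table, the four fitted
models with coefficient tables, discrimination/calibration reports for the
derivation and validation sets, a cohort summary, and a manifest stamping
every artifact with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import elixhauser
from .elixhauser import DEFAULT_EXCLUSIONS
from .evaluation import EvaluationReport, evaluate_model, plot_roc
from .modeling import FittedModel, coefficient_table, fit_linear, fit_logistic, predict, split_sample
from .outcomes import EscalationConfig, OutcomeSet, build_outcomes, outcomes_frame
from .records import Hospitalization, read_hospitalizations, validate_dataset, write_hospitalizations
from .synthetic import GeneratorConfig, generate_records

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "summarize_cohort", "OUTCOME_COLUMNS"]

logger = logging.getLogger(__name__)

#: outcome name -> (column of the outcome frame, model family)
OUTCOME_COLUMNS: dict[str, tuple[str, str]] = {
    "mortality": ("died", "logistic"),
    "escalation": ("escalation", "logistic"),
    "readmission": ("readmit_30d", "logistic"),
    "log_los": ("log_los", "linear"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    out_dir: str | Path = "casemix_run"
    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str | Path] = None
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    min_count: int = 0
    drg_screen: bool = False
    escalation: EscalationConfig = field(default_factory=EscalationConfig)
    split_fraction: float = 0.7
    split_seed: int = 0
    outcomes: tuple[str, ...] = ("mortality", "escalation", "readmission", "log_los")
    hl_groups: int = 10
    make_plots: bool = False
    write_data: bool = False

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_dir is None):
            raise ValueError("supply exactly one of generator config or input_dir")
        unknown = [o for o in self.outcomes if o not in OUTCOME_COLUMNS]
        if unknown:
            raise ValueError(f"unknown outcome(s): {unknown}")

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set, tuple, list)):
                return sorted(map(str, obj)) if isinstance(obj, (set, frozenset)) else [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj
        payload = {k: v for k, v in enc(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    models: dict[str, FittedModel]
    reports: dict[str, EvaluationReport]
    prevalence: pd.DataFrame
    summary: dict
    artifacts: dict[str, Path]
    n_records: int


def summarize_cohort(
    records: Sequence[Hospitalization], outcome_map: Mapping[str, OutcomeSet]
) -> dict:
    """Cohort-characteristics summary: counts, percents, medians with IQR."""
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    ages = np.array([r.age_years for r in records])
    frame = outcomes_frame(outcome_map)
    los = frame["los_days"].to_numpy()

    def pct(x: float) -> float:
        return round(100.0 * x / n, 1)

    def med_iqr(v: np.ndarray) -> dict:
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        return {"median": round(float(q2), 1), "iqr": [round(float(q1), 1), round(float(q3), 1)]}

    return {
        "n": n,
        "male_pct": pct(sum(1 for r in records if r.sex == "male")),
        "age_years": med_iqr(ages),
        "los_days": med_iqr(los),
        "mortality_pct": pct(int(frame["died"].sum())),
        "escalation_pct": pct(int(frame["escalation"].sum())),
        "readmission_30d_pct": pct(int(frame["readmit_30d"].sum())),
        "emergency_admission_pct": pct(
            sum(1 for r in records if r.admission_source == "emergency")),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run generate/ingest -> map -> outcomes -> split -> fit -> evaluate."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    definitions = elixhauser.load_definitions()

    # --- stage 1: cohort ----------------------------------------------------
    if cfg.generator is not None:
        records, _truth = generate_records(cfg.generator)
        logger.info("generated %d hospitalizations (seed %d)", len(records), cfg.generator.seed)
        if cfg.write_data:
            write_hospitalizations(records, out_dir / "data")
    else:
        result = read_hospitalizations(cfg.input_dir)
        records = result.records
        logger.info("read %d hospitalizations, rejected %d rows",
                    len(records), result.n_rejected)
    report = validate_dataset(records)
    if report.n_violations:
        logger.warning("dataset validation found %d violation(s)", report.n_violations)

    # --- stage 2: comorbidity flags -----------------------------------------
    ids = [r.hospitalization_id for r in records]
    flags = elixhauser.assign_flags_table(
        [list(r.diagnosis_codes) for r in records], definitions, index=ids)
    flags = elixhauser.apply_hierarchy_table(flags)
    if cfg.drg_screen:
        flags = elixhauser.apply_drg_screen_table(
            flags, [r.drg for r in records], definitions)
    prevalence = elixhauser.prevalence_table(flags)
    conditions = elixhauser.select_conditions(prevalence, cfg.exclusions, cfg.min_count)
    X = elixhauser.design_matrix(flags, conditions)
    logger.info("flagged %d conditions; %d enter the design matrix",
                len(definitions), len(conditions))

    # --- stage 3: outcomes --------------------------------------------------
    outcome_map = build_outcomes(records, cfg.escalation)
    y = outcomes_frame(outcome_map).loc[ids]

    # --- stage 4: split -----------------------------------------------------
    split = split_sample(ids, cfg.split_fraction, cfg.split_seed)
    der_mask = np.array([i in split.derivation_ids for i in ids])
    X_der, X_val = X[der_mask], X[~der_mask]
    y_der, y_val = y[der_mask], y[~der_mask]
    logger.info("split %d/%d (fraction %.2f, seed %d)",
                der_mask.sum(), (~der_mask).sum(), cfg.split_fraction, cfg.split_seed)

    # --- stage 5: fit + evaluate --------------------------------------------
    models: dict[str, FittedModel] = {}
    reports: dict[str, EvaluationReport] = {}
    names = elixhauser.display_names(definitions)
    artifacts: dict[str, Path] = {}
    for outcome in cfg.outcomes:
        col, family = OUTCOME_COLUMNS[outcome]
        fit = fit_logistic if family == "logistic" else fit_linear
        model = fit(X_der, y_der[col].astype(float), outcome=outcome)
        models[outcome] = model
        reports[outcome] = evaluate_model(
            model, (X_der, y_der[col].astype(float)), (X_val, y_val[col].astype(float)),
            hl_groups=cfg.hl_groups)
        table = coefficient_table(model, names)
        path = out_dir / f"coefficients_{outcome}.csv"
        table.to_csv(path, index=False)
        artifacts[f"coefficients_{outcome}"] = path
        if cfg.make_plots and family == "logistic":
            plot_path = out_dir / f"roc_{outcome}.png"
            plot_roc({
                f"{outcome} derivation": (predict(model, X_der), y_der[col].astype(float)),
                f"{outcome} validation": (predict(model, X_val), y_val[col].astype(float)),
            }, str(plot_path))
            artifacts[f"roc_{outcome}"] = plot_path

    # --- stage 6: artifacts -------------------------------------------------
    summary = summarize_cohort(records, outcome_map)
    meta = {
        "config_hash": cfg.config_hash(),
        "split_seed": cfg.split_seed,
        "generator_seed": cfg.generator.seed if cfg.generator else None,
        "n_records": len(records),
        "derivation_n": int(der_mask.sum()),
        "validation_n": int((~der_mask).sum()),
        "conditions": conditions,
    }
    writes = {
        "prevalence": ("prevalence.csv", lambda p: prevalence.to_csv(p, index=False)),
        "models": ("models.json", lambda p: p.write_text(json.dumps(
            {"meta": meta, "models": {k: m.to_dict() for k, m in models.items()}}, indent=2))),
        "evaluation": ("evaluation.json", lambda p: p.write_text(json.dumps(
            {"meta": meta, "evaluation": {k: r.to_dict() for k, r in reports.items()}}, indent=2))),
        "summary": ("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2))),
    }
    for key, (name, writer) in writes.items():
        path = out_dir / name
        writer(path)
        artifacts[key] = path
    manifest = {
        "meta": meta,
        "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest_path

    return PipelineResult(models, reports, prevalence, summary, artifacts, len(records))
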