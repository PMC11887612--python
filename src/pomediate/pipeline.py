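"""End-to-end orchestration: generate -> prepare -> infer -> report.

A single declarative config document (YAML or dict) drives the run. Three
input modes are supported, exactly one per run:

* ``records``     — delimited record-level births; the deletion rules and
                    mediator derivation run first;
* ``cell-counts`` — a pre-aggregated eight-cell table per outcome;
* ``simulate``    — the synthetic generator, at record or cell level, with
                    cell probabilities given directly or calibrated from
                    effect-size targets.

Artifacts written to the output directory: ``deletion_log.json`` (record
inputs), ``prevalence.tsv``, ``report.tsv`` (TE per 1000 and PA per margin,
per outcome) and ``manifest.json`` (config echo, seed, library versions).
With a fixed seed every artifact is byte-identical across runs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from .mediation_effects import run_analysis
from .record_prep import (
    OUTCOMES,
    ClassificationRules,
    PrevalenceTable,
    aggregate,
    filter_records,
    prevalence_table,
    read_cell_counts,
    read_records,
    write_cell_counts,
)
from .synthetic_data import (
    CellProbs,
    GeneratorConfig,
    calibrate_cell_probs,
    simulate_cell_counts,
    simulate_records,
)

logger = logging.getLogger(__name__)

MODES = ("records", "cell-counts", "simulate")


class ConfigurationError(ValueError):
    """Aggregated, human-readable config validation failures."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n- " + "\n- ".join(self.errors))


@dataclass
class PipelineConfig:
    mode: str
    input_path: str | None = None
    column_map: Mapping[str, str] | None = None
    units: str = "metric"
    sentinels: tuple = ()
    rules: ClassificationRules = dc_field(default_factory=ClassificationRules)
    draws: int = 10_000
    burn_in: int = 5_000
    chains: int = 2
    engine: str = "conjugate"
    seed: int = 0
    output_dir: str = "results"
    simulate: dict | None = None
    raw: dict = dc_field(default_factory=dict)


def default_config() -> dict:
    """Packaged simulate-mode config: the five outcomes calibrated to the
    published total effects and all three published PA scenarios, at
    study-scale cohort sizes, cell level."""
    return {
        "mode": "simulate",
        "draws": 10_000,
        "burn_in": 5_000,
        "chains": 2,
        "engine": "conjugate",
        "seed": 0,
        "output_dir": "results",
        "simulate": {
            "level": "cell",
            "n_per_race": {"non_black": ref.N_NON_BLACK, "black": ref.N_BLACK},
            "prevalence_percent": {
                "non_black": list(ref.PREVALENCE_PERCENT["non_black"]),
                "black": list(ref.PREVALENCE_PERCENT["black"]),
            },
            "normalize_prevalence": True,
            "missing_rates": {},
            "outcomes": {
                name: {
                    "baseline": ref.BASELINE_RATE[name],
                    "total_effect": ref.total_effect_target(name),
                    "cde": {m: ref.cde_target(name, m) for m in ("M1", "M2", "M1M2")},
                }
                for name in OUTCOMES
            },
        },
    }


def _check_positive_int(value, name, minimum, errors):
    try:
        v = int(value)
    except (TypeError, ValueError):
        errors.append(f"{name} must be an integer, got {value!r}")
        return None
    if v < minimum:
        errors.append(f"{name} must be >= {minimum}, got {v}")
        return None
    return v


def validate_config(document: Mapping) -> PipelineConfig:
    """Validate a parsed config document; every violation is reported at once."""
    errors: list[str] = []
    doc = dict(document or {})

    mode = doc.get("mode")
    if isinstance(mode, (list, tuple)):
        errors.append(f"exactly one input mode may be configured, got {list(mode)}")
        mode = None
    elif mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "simulate" and doc.get("input"):
        errors.append("exactly one input mode may be configured: "
                      "'simulate' does not take an input path")
    if mode in ("records", "cell-counts") and doc.get("simulate"):
        errors.append("exactly one input mode may be configured: "
                      f"{mode!r} conflicts with a 'simulate' section")

    draws = _check_positive_int(doc.get("draws", 10_000), "draws (S)", 100, errors)
    burn_in = _check_positive_int(doc.get("burn_in", 5_000), "burn_in", 0, errors)
    chains = _check_positive_int(doc.get("chains", 2), "chains", 1, errors)
    seed = _check_positive_int(doc.get("seed", 0), "seed", 0, errors)

    engine = doc.get("engine", "conjugate")
    if engine not in ("conjugate", "gibbs"):
        errors.append(f"engine must be 'conjugate' or 'gibbs', got {engine!r}")
    units = doc.get("units", "metric")
    if units not in ("metric", "imperial"):
        errors.append(f"units must be 'metric' or 'imperial', got {units!r}")

    rules_doc = doc.get("classification", {}) or {}
    rules = ClassificationRules()
    try:
        rules = ClassificationRules(**rules_doc)
    except TypeError as exc:
        errors.append(f"classification: {exc}")

    input_path = doc.get("input")
    if mode in ("records", "cell-counts") and not input_path:
        errors.append(f"mode {mode!r} requires an input path")

    sim = doc.get("simulate")
    if mode == "simulate":
        if not isinstance(sim, Mapping):
            errors.append("mode 'simulate' requires a 'simulate' section")
        else:
            sim = dict(sim)
            if sim.get("level", "cell") not in ("record", "cell"):
                errors.append("simulate.level must be 'record' or 'cell'")
            if not isinstance(sim.get("outcomes"), Mapping) or not sim.get("outcomes"):
                errors.append("simulate.outcomes must map outcome names to specs")
            prev = sim.get("prevalence_percent")
            if not isinstance(prev, Mapping) or set(prev) != {"non_black", "black"}:
                errors.append(
                    "simulate.prevalence_percent needs 'non_black' and 'black' 4-vectors"
                )

    if errors:
        raise ConfigurationError(errors)
    return PipelineConfig(
        mode=mode,
        input_path=input_path,
        column_map=doc.get("columns"),
        units=units,
        sentinels=tuple(doc.get("sentinels", ()) or ()),
        rules=rules,
        draws=draws,
        burn_in=burn_in,
        chains=chains,
        engine=engine,
        seed=seed,
        output_dir=str(doc.get("output_dir", "results")),
        simulate=dict(sim) if isinstance(sim, Mapping) else None,
        raw=doc,
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _generator_config(cfg: PipelineConfig) -> GeneratorConfig:
    sim = cfg.simulate
    prev = PrevalenceTable.from_percentages(
        sim["prevalence_percent"]["non_black"],
        sim["prevalence_percent"]["black"],
        normalize=bool(sim.get("normalize_prevalence", False)),
    )
    n_spec = sim["n_per_race"]
    if isinstance(n_spec, Mapping):
        n_per_race = {1: int(n_spec["non_black"]), 2: int(n_spec["black"])}
    else:
        n_per_race = int(n_spec)
    cell_probs = {}
    for name, spec in sim["outcomes"].items():
        if "cell_probs" in spec:
            cp = np.zeros((2, 2, 2))
            cp[0] = np.reshape(spec["cell_probs"]["non_black"], (2, 2))
            cp[1] = np.reshape(spec["cell_probs"]["black"], (2, 2))
            cell_probs[name] = CellProbs(cp)
        else:
            cell_probs[name] = calibrate_cell_probs(
                prev,
                te_target=spec["total_effect"],
                cde_targets=spec.get("cde"),
                baseline=spec["baseline"],
            )
    return GeneratorConfig(
        n_per_race=n_per_race,
        prevalence=prev,
        cell_probs=cell_probs,
        missing_rates=dict(sim.get("missing_rates", {})),
        seed=cfg.seed,
        level=sim.get("level", "cell"),
    )


@dataclass
class PipelineResult:
    report: pd.DataFrame
    prevalence: PrevalenceTable
    deletion_log: object | None
    artifacts: dict


def prepare_cells(cfg: PipelineConfig):
    """Resolve the configured input mode into per-outcome cell counts.

    Returns (cells_by_outcome, prevalence, deletion_log)."""
    deletion_log = None
    if cfg.mode == "records":
        records = read_records(
            cfg.input_path, column_map=cfg.column_map, units=cfg.units,
            sentinels=cfg.sentinels,
        )
        derived, deletion_log = filter_records(records, rules=cfg.rules)
        outcomes = [c for c in OUTCOMES if c in derived.columns]
        cells = {name: aggregate(derived, name) for name in outcomes}
    elif cfg.mode == "cell-counts":
        cells = read_cell_counts(cfg.input_path)
    else:  # simulate
        gen = _generator_config(cfg)
        if gen.level == "record":
            records = simulate_records(gen)
            derived, deletion_log = filter_records(records)
            cells = {name: aggregate(derived, name) for name in gen.outcome_probs()}
        else:
            cells = simulate_cell_counts(gen)
            if not isinstance(cells, dict):
                cells = {cells.outcome: cells}
    prevalence = prevalence_table(next(iter(cells.values())))
    return cells, prevalence, deletion_log


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured run and write all artifacts."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, prevalence, deletion_log = prepare_cells(cfg)
    report = run_analysis(
        cells, S=cfg.draws, seed=cfg.seed, engine=cfg.engine,
        burn_in=cfg.burn_in, chains=cfg.chains,
    )

    artifacts = {}
    report_path = outdir / "report.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
    artifacts["report"] = str(report_path)

    prev_path = outdir / "prevalence.tsv"
    prevalence.to_tsv(prev_path)
    artifacts["prevalence"] = str(prev_path)

    if deletion_log is not None:
        log_path = outdir / "deletion_log.json"
        deletion_log.to_json(log_path)
        artifacts["deletion_log"] = str(log_path)

    counts_path = outdir / "cell_counts.csv"
    write_cell_counts(cells, counts_path)
    artifacts["cell_counts"] = str(counts_path)

    import scipy

    from . import __version__

    manifest = {
        "config": cfg.raw,
        "seed": cfg.seed,
        "versions": {
            "pomediate": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    artifacts["manifest"] = str(manifest_path)

    logger.info("pipeline complete; artifacts in %s", outdir)
    return PipelineResult(
        report=report, prevalence=prevalence, deletion_log=deletion_log,
        artifacts=artifacts,
    )
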