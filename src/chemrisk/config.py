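"""Run configuration, deterministic seed derivation, and artifact writing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import benchmark as bm
from . import extraction, selection
from .datagen import GeneratorConfig, generate_dataset, write_dataset
from .selection import PipelineConfig

log = logging.getLogger("chemrisk")


class ConfigError(ValueError):
    """Schema violation in a run configuration; the message names the field."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class BenchmarkConfig:
    panel: str = "criteria"
    classifiers: tuple[str, ...] = ("SVC", "MLP")
    folds: int = 5
    repeats: int = 10


@dataclass
class RunConfig:
    """Flat configuration of a full generate-fit-select-benchmark run."""

    seed: int = 0
    out_dir: str = "chemrisk_run"
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    selection: PipelineConfig = field(default_factory=PipelineConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    extraction_method: str = "pca"
    criterion: str = "beta"
    run_benchmark: bool = False


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise ConfigError(f"unknown field: {where}")
        ftype = fields[key].type
        if isinstance(value, dict) and ftype in (
            "GeneratorConfig",
            "PipelineConfig",
            "BenchmarkConfig",
        ):
            sub_cls = {
                "GeneratorConfig": GeneratorConfig,
                "PipelineConfig": PipelineConfig,
                "BenchmarkConfig": BenchmarkConfig,
            }[ftype]
            kwargs[key] = _build(sub_cls, value, where)
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid configuration at {path or 'top level'}: {exc}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown fields are rejected with their full field path.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(RunConfig, data, "")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 12):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(path: Path, payload: dict, config: RunConfig | None = None) -> None:
    """Serialize an artifact with fixed float precision and a config hash."""
    if config is not None:
        payload = {"config_hash": config_hash(config), **payload}
    path.write_text(json.dumps(_round_floats(payload), indent=1, sort_keys=True))


def model_to_dict(model: extraction.ExtractionModel) -> dict:
    return {
        "method": model.method,
        "eigenvalues": model.eigenvalues,
        "eigenvectors": model.eigenvectors,
        "loadings": model.loadings,
        "explained_variance_fraction": model.explained_variance_fraction,
        "params": {k: v for k, v in model.params.items()},
        "feature_names": model.feature_names,
    }


def selection_to_dict(sel: selection.SelectionResult) -> dict:
    diag = {
        k: v
        for k, v in sel.diagnostics.items()
        if not isinstance(v, np.ndarray)
    }
    return {
        "criterion": sel.criterion,
        "M_retained": sel.M_retained,
        "assignment": sel.assignment,
        "retained_features": sel.retained_features,
        "diagnostics": diag,
    }


def run(config: RunConfig) -> Path:
    """Execute generate -> fit -> select (-> benchmark) -> artifacts on disk.

    Re-running with the same configuration reproduces byte-identical JSON
    artifacts (floats serialized at fixed precision).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    try:
        gen_cfg = dataclasses.replace(
            config.generator, seed=derive_seed(config.seed, "generate")
        )
        log.info("generating dataset: %d x %d", gen_cfg.n_samples, gen_cfg.n_features)
        table, truth = generate_dataset(gen_cfg)
        write_dataset(table, out / "dataset.csv")
        write_json(
            out / "ground_truth.json",
            {
                "informative_set": truth.informative_set,
                "nonlinear_features": truth.nonlinear_features,
                "generator": dataclasses.asdict(gen_cfg),
            },
            config,
        )
        sel_cfg = dataclasses.replace(
            config.selection, seed=derive_seed(config.seed, "select")
        )
        sel, model = selection.run_selection_pipeline(
            table, config.extraction_method, config.criterion, sel_cfg
        )
        log.info(
            "selection: criterion=%s M=%d features=%d",
            config.criterion,
            sel.M_retained,
            len(sel.retained_features),
        )
        write_json(out / "model.json", model_to_dict(model), config)
        write_json(out / "selection.json", selection_to_dict(sel), config)
        if config.run_benchmark:
            report = bm.run_benchmark(
                table,
                methods=bm.standard_methods(config.benchmark.panel),
                classifiers=list(config.benchmark.classifiers),
                folds=config.benchmark.folds,
                repeats=config.benchmark.repeats,
                seed=derive_seed(config.seed, "benchmark"),
            )
            (out / "report.csv").write_text(bm.render_report(report, "csv"))
            write_json(
                out / "report.json",
                {
                    "bac_mean": report.bac_mean.to_dict(),
                    "marks": report.marks,
                },
                config,
            )
        return out
    finally:
        log.removeHandler(fh)
        fh.close()
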