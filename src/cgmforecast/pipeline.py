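"""End-to-end pipeline orchestration with deterministic seeding.

``run_pipeline`` executes simulate/read -> smooth (train and test files
independently) -> featurize -> train -> predict -> evaluate, writing every
intermediate artifact plus a manifest (config hash, seed, versions, artifact
paths) sufficient to re-run any stage in isolation.

One global seed fans out to per-stage seeds through a fixed hash derivation,
so stages are independently re-runnable yet jointly deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_model import PatientSeries, read_csv, read_ohio_xml, write_csv, write_ohio_xml
from .evaluation import EvalReport, evaluate
from .features import build_windows
from .forecaster import ForecastResults, GlucoseForecaster, ModelConfig
from .kalman import smooth_cgm
from .synthetic import FaultSpec, SimulationConfig, generate_patient


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across runs and platforms)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Structured configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    train_path: str | None = None  # CSV/XML; None -> simulate
    test_path: str | None = None
    train_days: int = 10
    test_days: int = 3
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    smoothing: dict = field(default_factory=dict)  # q, r, p0
    L: int = 24
    PH_minutes: int = 30
    glucose_channel: str = "smoothed"
    event_mode: str = "replace"
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    reference: str = "raw"
    compare_channels: bool = False  # also run the other glucose channel

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_series(path) -> PatientSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if path.suffix.lower() == ".xml":
        return read_ohio_xml(path)
    return read_csv(path)


def write_series(series: PatientSeries, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".xml":
        write_ohio_xml(series, path)
    else:
        write_csv(series, path)


def save_model(results: ForecastResults, path) -> None:
    results.network._cache = None  # noqa: SLF001 - drop transient training caches
    for layer in results.network._layers():
        layer._cache = None
    with open(path, "wb") as fh:
        pickle.dump(results, fh)


def load_model(path) -> ForecastResults:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def _simulate_pair(config: PipelineConfig) -> tuple[PatientSeries, PatientSeries]:
    base = dict(config.simulation)
    fault = base.pop("fault_spec", None)
    if isinstance(fault, dict):
        base["fault_spec"] = FaultSpec(**fault)
    train_cfg = SimulationConfig(
        **{**base, "seed": derive_seed(config.seed, "simulate-train"), "days": config.train_days,
           "patient_id": "sim-train"}
    )
    test_cfg = SimulationConfig(
        **{**base, "seed": derive_seed(config.seed, "simulate-test"), "days": config.test_days,
           "patient_id": "sim-test"}
    )
    return generate_patient(train_cfg), generate_patient(test_cfg)


def run_pipeline(config: PipelineConfig) -> list[EvalReport]:
    """Execute the full pipeline; returns one EvalReport per glucose channel run."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"cgmforecast": __version__, "numpy": np.__version__},
        "artifacts": {},
    }
    stage = "input"
    try:
        if config.train_path or config.test_path:
            if not (config.train_path and config.test_path):
                raise ValueError("provide both train_path and test_path, or neither")
            train_series = read_series(config.train_path)
            test_series = read_series(config.test_path)
        else:
            train_series, test_series = _simulate_pair(config)
        for name, series in (("train", train_series), ("test", test_series)):
            p = out / f"{name}_series.csv"
            write_csv(series, p)
            manifest["artifacts"][f"{name}_series"] = str(p)

        stage = "smooth"
        smooth_kw = dict(config.smoothing)
        train_smoothed = smooth_cgm(train_series, **smooth_kw).mean
        test_smoothed = smooth_cgm(test_series, **smooth_kw).mean

        reports: list[EvalReport] = []
        channels = [config.glucose_channel]
        if config.compare_channels:
            channels.append("smoothed" if config.glucose_channel == "raw" else "raw")
        PH = config.PH_minutes // 5
        for channel in channels:
            stage = f"featurize[{channel}]"
            windows = build_windows(
                train_series,
                glucose_channel=channel,
                L=config.L,
                PH=PH,
                smoothed=train_smoothed if channel == "smoothed" else None,
                event_mode=config.event_mode,
            )
            stage = f"train[{channel}]"
            model_cfg = ModelConfig(**{"seed": derive_seed(config.seed, f"train-{channel}"),
                                       **config.model})
            results = GlucoseForecaster(windows, model_cfg).fit()
            model_path = out / f"model_{channel}.pkl"
            save_model(results, model_path)
            manifest["artifacts"][f"model_{channel}"] = str(model_path)

            stage = f"evaluate[{channel}]"
            report = evaluate(
                results,
                test_series,
                PH_minutes=config.PH_minutes,
                glucose_channel=channel,
                reference=config.reference,
            )
            rp = out / f"eval_{channel}.json"
            rp.write_text(report.to_json())
            manifest["artifacts"][f"eval_{channel}"] = str(rp)
            reports.append(report)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc} (artifacts so far recorded in "
            f"{out / 'manifest.json'})"
        ) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return reports
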