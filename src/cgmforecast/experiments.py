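"""Reproducible desk-scale experiments on synthetic patients.

These routines bundle the study designs the package ships with:

* ``sensor_correction_experiment`` — does Kalman smoothing move the CGM
  channel closer to the true blood glucose than the raw, fault-laden sensor
  trace? (directional raw-vs-smoothed comparison, many seeds)
* ``forecast_skill_experiment`` — does the stacked-LSTM forecaster beat the
  persistence baseline on a held-out simulated record, and does the
  smoothed-glucose input channel beat the raw one?

The neural experiments use a desk-scale profile (stacked two-layer LSTM with
32 hidden units and a 64/32 dense head, 30 simulated training days + 3 test
days, 200-epoch cap with early stopping) so a full multi-seed study runs in
minutes on one CPU core; the full-width configuration of
:class:`~cgmforecast.forecaster.ModelConfig` remains the library default.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data_model import PatientSeries
from .evaluation import EvalReport, evaluate, rmse
from .features import build_windows
from .forecaster import GlucoseForecaster, ModelConfig
from .kalman import smooth_cgm
from .pipeline import derive_seed
from .synthetic import SimulationConfig, generate_patient

#: desk-scale training profile used by the shipped experiments
DESK_MODEL = ModelConfig(
    hidden_units=32,
    dense_sizes=(64, 32),
    dense_activations=("relu", "relu"),
    max_epochs=200,
    patience=25,
)
DESK_TRAIN_DAYS = 30
DESK_TEST_DAYS = 3


def simulate_train_test(
    seed: int,
    train_days: int = DESK_TRAIN_DAYS,
    test_days: int = DESK_TEST_DAYS,
    **overrides,
) -> tuple[PatientSeries, PatientSeries]:
    """Simulate independent train/test records for one study seed."""
    train = generate_patient(
        SimulationConfig(
            seed=derive_seed(seed, "exp-train"), days=train_days, patient_id="sim-train", **overrides
        )
    )
    test = generate_patient(
        SimulationConfig(
            seed=derive_seed(seed, "exp-test"), days=test_days, patient_id="sim-test", **overrides
        )
    )
    return train, test


def sensor_correction_trial(seed: int, days: int = 7) -> dict:
    """RMSE of raw and smoothed CGM against true blood glucose for one seed.

    Compared on slots where the raw sensor reported a value, so raw and
    smoothed are scored on the same support.
    """
    series = generate_patient(SimulationConfig(seed=seed, days=days))
    sm = smooth_cgm(series)
    mask = np.isfinite(series.cgm)
    raw = rmse(series.cgm[mask], series.truth_bg[mask])
    smoothed = rmse(sm.mean[mask], series.truth_bg[mask])
    return {"seed": seed, "rmse_raw": raw, "rmse_smoothed": smoothed, "n": int(mask.sum())}


def sensor_correction_experiment(seeds: list[int], days: int = 7) -> dict:
    """Run :func:`sensor_correction_trial` over seeds; report the win count."""
    trials = [sensor_correction_trial(s, days) for s in seeds]
    wins = sum(t["rmse_smoothed"] < t["rmse_raw"] for t in trials)
    return {
        "trials": trials,
        "wins": wins,
        "n_seeds": len(seeds),
        "mean_rmse_raw": float(np.mean([t["rmse_raw"] for t in trials])),
        "mean_rmse_smoothed": float(np.mean([t["rmse_smoothed"] for t in trials])),
    }


def forecast_skill_trial(
    seed: int,
    glucose_channel: str = "smoothed",
    PH_minutes: int = 30,
    model: ModelConfig | None = None,
    train_days: int = DESK_TRAIN_DAYS,
    test_days: int = DESK_TEST_DAYS,
) -> EvalReport:
    """Train on one simulated record, evaluate against truth on a held-out one."""
    model = model or DESK_MODEL
    train_series, test_series = simulate_train_test(seed, train_days, test_days)
    smoothed = smooth_cgm(train_series).mean if glucose_channel == "smoothed" else None
    windows = build_windows(
        train_series, glucose_channel=glucose_channel, L=24, PH=PH_minutes // 5, smoothed=smoothed
    )
    # one init/batch-order seed per study seed, shared across channel arms,
    # so channel comparisons are paired rather than confounded by init noise
    cfg = replace(model, seed=derive_seed(seed, "fit"))
    results = GlucoseForecaster(windows, cfg).fit()
    return evaluate(
        results, test_series, PH_minutes=PH_minutes, glucose_channel=glucose_channel,
        reference="truth",
    )


def forecast_skill_experiment(
    seeds: list[int], PH_minutes: int = 30, channels: tuple[str, ...] = ("smoothed", "raw")
) -> dict:
    """Multi-seed skill study: LSTM vs persistence, smoothed vs raw channel."""
    per_channel: dict[str, list[EvalReport]] = {c: [] for c in channels}
    for seed in seeds:
        for channel in channels:
            per_channel[channel].append(forecast_skill_trial(seed, channel, PH_minutes))
    out: dict = {"n_seeds": len(seeds), "PH_minutes": PH_minutes}
    for channel, reports in per_channel.items():
        out[channel] = {
            "forecast_rmse": [r.forecast_rmse for r in reports],
            "baseline_rmse": [r.baseline_rmse for r in reports],
            "mean_forecast_rmse": float(np.mean([r.forecast_rmse for r in reports])),
            "mean_baseline_rmse": float(np.mean([r.baseline_rmse for r in reports])),
            "beats_persistence": sum(r.forecast_rmse < r.baseline_rmse for r in reports),
        }
    if len(channels) == 2:
        a, b = channels
        out["smoothed_beats_raw"] = sum(
            ra.forecast_rmse < rb.forecast_rmse
            for ra, rb in zip(per_channel["smoothed"], per_channel["raw"])
        ) if "smoothed" in channels and "raw" in channels else None
    return out
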