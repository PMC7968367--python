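"""RMSE evaluation of sensor correction and forecasts, plus a persistence baseline.

Two criteria are computed.  Sensor accuracy pairs each fingerstick reading
(the ground-truth proxy in real data) with the raw or smoothed CGM value in
the same 5-minute slot and reports the RMSE over pairs.  Forecast accuracy
is the RMSE between predictive means at horizon ``PH`` and a chosen
reference channel: raw CGM, smoothed CGM, or — on synthetic data only — the
simulator's true blood glucose.

The persistence baseline predicts the last observed glucose of each history
window; any forecaster worth running must beat it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .data_model import GRID_MINUTES, PatientSeries
from .features import FeatureWindows, build_windows
from .forecaster import ForecastResult, ForecastResults
from .kalman import smooth_cgm


def rmse(pred, ref) -> float:
    """Root-mean-square error between paired series: sqrt(mean((pred - ref)^2))."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise ValueError("rmse of empty input is undefined")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(ref))):
        raise ValueError("rmse requires finite paired values")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def sensor_rmse(series: PatientSeries, glucose: np.ndarray) -> tuple[float, int]:
    """RMSE of a glucose channel against fingerstick readings (same-slot pairing).

    Returns ``(rmse, n_dropped)`` where ``n_dropped`` counts fingersticks at
    indices with no defined glucose value.
    """
    glucose = np.asarray(glucose, dtype=float)
    pairs = [(glucose[i], v) for i, v in series.fingerstick if np.isfinite(glucose[i])]
    dropped = len(series.fingerstick) - len(pairs)
    if not pairs:
        raise ValueError("no usable fingerstick/glucose pairs")
    y, x = zip(*pairs)
    return rmse(np.array(y), np.array(x)), dropped


def persistence_baseline(windows: FeatureWindows) -> ForecastResult:
    """Naive forecaster: predict each window's last observed glucose value.

    The predictive sd is the residual sd of this rule over the provided
    windows' own targets.
    """
    if windows.n_windows == 0:
        raise ValueError("persistence baseline needs at least one window")
    mean = windows.last_glucose().astype(float)
    resid = windows.targets - mean
    sd = float(np.std(resid)) if len(resid) > 1 else 1.0
    return ForecastResult(
        mean=mean,
        sd=np.full_like(mean, max(sd, 1e-9)),
        target_index=windows.target_index.copy(),
    )


@dataclass
class EvalReport:
    """Per-patient, per-horizon, per-configuration RMSE summary."""

    patient_id: str
    PH_minutes: int
    glucose_channel: str
    reference: str
    forecast_rmse: float
    baseline_rmse: float
    n_points: int
    sensor_rmse_raw: float | None = None
    sensor_rmse_smoothed: float | None = None
    best_validation_nll: float | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)


def _reference_values(
    series: PatientSeries, reference: str, smoothed_mean: np.ndarray | None, idx: np.ndarray
) -> np.ndarray:
    if reference == "raw":
        ref = series.cgm
    elif reference == "smoothed":
        if smoothed_mean is None:
            raise ValueError("smoothed reference requested but no smoothed series available")
        ref = smoothed_mean
    elif reference == "truth":
        if series.truth_bg is None:
            raise ValueError("truth reference is only available on simulated data")
        ref = series.truth_bg
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return np.asarray(ref, dtype=float)[idx]


def evaluate(
    trained: ForecastResults,
    test_series: PatientSeries,
    PH_minutes: int = 30,
    glucose_channel: str | None = None,
    reference: str = "raw",
) -> EvalReport:
    """Score a fitted forecaster on an independent test file.

    The test series is smoothed in its own right (never jointly with the
    training file), featurized with the *training* scaler, forecast at
    ``PH_minutes``, and scored against ``reference``.  Passing the training
    file itself is rejected as leakage.
    """
    if PH_minutes % GRID_MINUTES != 0 or PH_minutes < GRID_MINUTES:
        raise ValueError(f"PH must be a positive multiple of {GRID_MINUTES} minutes")
    PH = PH_minutes // GRID_MINUTES
    if PH != trained.PH:
        raise ValueError(f"model was trained for PH={trained.PH} indices, requested {PH}")
    if trained.train_fingerprint is not None and test_series.fingerprint() == trained.train_fingerprint:
        raise ValueError(
            "leakage: test series is the training series; evaluate on a separate file"
        )
    channel = glucose_channel or trained.glucose_channel
    smoothed_mean = None
    sm_rmse = raw_rmse = None
    needs_smooth = channel == "smoothed" or reference == "smoothed" or series_has_fs(test_series)
    if needs_smooth and np.isfinite(test_series.cgm).sum() >= 2:
        smoothed_mean = smooth_cgm(test_series).mean
    if series_has_fs(test_series):
        try:
            raw_rmse = sensor_rmse(test_series, test_series.cgm)[0]
        except ValueError:
            raw_rmse = None
        if smoothed_mean is not None:
            sm_rmse = sensor_rmse(test_series, smoothed_mean)[0]
    windows = build_windows(
        test_series,
        glucose_channel=channel,
        L=trained.L,
        PH=PH,
        scaler=trained.scaler,
        smoothed=smoothed_mean,
    )
    if windows.n_windows == 0:
        raise ValueError("test series yields no evaluable windows")
    forecast = trained.predict(windows)
    ref_vals = _reference_values(test_series, reference, smoothed_mean, windows.target_index)
    keep = np.isfinite(ref_vals)
    baseline = persistence_baseline(windows)
    return EvalReport(
        patient_id=test_series.patient_id,
        PH_minutes=PH_minutes,
        glucose_channel=channel,
        reference=reference,
        forecast_rmse=rmse(forecast.mean[keep], ref_vals[keep]),
        baseline_rmse=rmse(baseline.mean[keep], ref_vals[keep]),
        n_points=int(keep.sum()),
        sensor_rmse_raw=raw_rmse,
        sensor_rmse_smoothed=sm_rmse,
        best_validation_nll=trained.best_validation_nll,
    )


def series_has_fs(series: PatientSeries) -> bool:
    return len(series.fingerstick) > 0


def plot_forecast(
    forecast: ForecastResult, series: PatientSeries, path, reference: str = "raw"
) -> None:
    """Prediction curve with a +-1 sd band over the raw CGM dots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    idx = forecast.target_index
    ref = series.truth_bg if (reference == "truth" and series.truth_bg is not None) else series.cgm
    ax.plot(np.arange(series.n_index), ref, ".", ms=3, color="tab:red", label=reference)
    ax.plot(idx, forecast.mean, color="tab:blue", lw=1.5, label="prediction")
    ax.fill_between(
        idx,
        forecast.mean - forecast.sd,
        forecast.mean + forecast.sd,
        color="tab:blue",
        alpha=0.25,
        label="+-1 sd",
    )
    ax.set_xlabel("grid index (5 min)")
    ax.set_ylabel("glucose (mg/dl)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
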