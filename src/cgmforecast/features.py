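"""Physiological feature crafting and supervised window assembly.

The forecaster consumes four input channels per 5-minute grid index:

* glucose — raw or Kalman-smoothed CGM (mg/dl),
* effective carbohydrate ``C_eff`` — a piecewise-linear meal-absorption proxy:
  glucose appearance is ignored for the first 15 min after a meal, rises
  linearly to the full meal amount over the next 45 min (9 grid indices at
  rate ``beta_inc = 0.111`` per index), then decays linearly back to zero
  over roughly 3 h (``beta_dec = 0.028`` per index),
* effective bolus insulin ``I_eff`` — insulin on board decaying linearly at
  ``R_insulin = 5 * 0.014 = 0.07`` units per index (the 5-minute aggregate of
  a 0.014/min population absorption rate), with no absorption delay,
* weighted step count ``S_avg`` — a triangular-weighted average of the last
  50 min of 5-minute step aggregates, emphasizing recent activity.

``build_windows`` turns these channels into supervised tensors: a history of
``L`` consecutive fully-observed indices as input and the glucose value
``PH`` indices past the window end as target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import PatientSeries

#: carbohydrate kinetics defaults (per 5-min grid index)
BETA_INC = 0.111
BETA_DEC = 0.028
CARB_LAG_INDICES = 3  # first 15 min after a meal contribute nothing
CARB_RISE_INDICES = 9  # rise spans the remaining 45 min of the first hour

#: insulin-on-board linear decrement per grid index (units / index)
R_INSULIN = 5 * 0.014

#: step-feature window length (10 indices = 50 min)
STEP_WINDOW = 10

CHANNEL_NAMES = ("glucose", "carbs_eff", "insulin_eff", "steps_avg")


@dataclass(frozen=True)
class CarbParams:
    beta_inc: float = BETA_INC
    beta_dec: float = BETA_DEC
    lag_indices: int = CARB_LAG_INDICES
    rise_indices: int = CARB_RISE_INDICES

    @property
    def peak_elapsed(self) -> int:
        """Elapsed indices from the meal at which C_eff peaks (end of the rise)."""
        return self.lag_indices + self.rise_indices


def _carb_response(elapsed: np.ndarray, grams: float, p: CarbParams) -> np.ndarray:
    """C_eff contribution of a single meal, per elapsed index (vectorized)."""
    out = np.zeros_like(elapsed, dtype=float)
    rising = (elapsed > p.lag_indices) & (elapsed <= p.peak_elapsed)
    out[rising] = np.minimum(grams, (elapsed[rising] - p.lag_indices) * p.beta_inc * grams)
    falling = elapsed > p.peak_elapsed
    d = elapsed[falling] - p.peak_elapsed  # decay clock starts at the peak
    out[falling] = np.maximum(0.0, grams * (1.0 - d * p.beta_dec))
    return out


def effective_carbs(
    meal_events: list[tuple[int, float]],
    n_index: int,
    params: CarbParams | None = None,
    mode: str = "replace",
) -> np.ndarray:
    """Per-index effective carbohydrate (grams) from sparse meal events.

    ``mode="replace"`` (default) tracks only the most recent meal: a new meal
    overwrites the tracked ``(t_meal, C_meal)`` pair and any unconsumed
    remainder of the previous meal is discarded.  ``mode="superpose"`` sums
    the responses of all meals instead (sensitivity-analysis variant).
    """
    p = params or CarbParams()
    if mode not in ("replace", "superpose"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros(n_index)
    events = sorted(meal_events)
    for k, (t_meal, grams) in enumerate(events):
        if grams < 0:
            raise ValueError(f"negative meal grams {grams} at index {t_meal}")
        if mode == "replace":
            end = events[k + 1][0] if k + 1 < len(events) else n_index
        else:
            end = n_index
        span = np.arange(t_meal, end)
        resp = _carb_response(span - t_meal, grams, p)
        if mode == "replace":
            out[t_meal:end] = resp
        else:
            out[t_meal:end] += resp
    return np.maximum(out, 0.0)


def effective_insulin(
    bolus_events: list[tuple[int, float]],
    n_index: int,
    r_insulin: float = R_INSULIN,
    mode: str = "replace",
) -> np.ndarray:
    """Per-index effective bolus insulin (units): linear decay at ``r_insulin``/index.

    The most recent bolus replaces the tracked ``(t_bolus, I_bolus)`` pair
    (or responses superpose with ``mode="superpose"``); there is no
    absorption delay.
    """
    if r_insulin <= 0:
        raise ValueError("r_insulin must be positive")
    if mode not in ("replace", "superpose"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros(n_index)
    events = sorted(bolus_events)
    for k, (t_bolus, units) in enumerate(events):
        if units < 0:
            raise ValueError(f"negative bolus {units} at index {t_bolus}")
        end = events[k + 1][0] if (mode == "replace" and k + 1 < len(events)) else n_index
        span = np.arange(t_bolus, end)
        resp = np.maximum(0.0, units - (span - t_bolus) * r_insulin)
        if mode == "replace":
            out[t_bolus:end] = resp
        else:
            out[t_bolus:end] += resp
    return out


def step_feature(steps: np.ndarray, n_index: int | None = None, n: int = STEP_WINDOW) -> np.ndarray:
    """Triangular-weighted trailing average of 5-minute step counts.

    ``S_avg(t) = (1/n) * sum_{i=0}^{n-1} (n - i) * steps(t - i)``; history
    before the start of the series counts as zero.
    """
    steps = np.asarray(steps, dtype=float)
    if n_index is None:
        n_index = len(steps)
    kernel = (n - np.arange(n)) / n  # weights 1.0, (n-1)/n, ..., 1/n
    return np.convolve(steps, kernel)[:n_index]


@dataclass
class ChannelScaler:
    """Per-channel z-score scaler fitted on training windows only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, inputs: np.ndarray) -> "ChannelScaler":
        flat = inputs.reshape(-1, inputs.shape[-1])
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant channels pass through centred
        return cls(mean=mean, sd=sd)

    def transform(self, inputs: np.ndarray) -> np.ndarray:
        return (inputs - self.mean) / self.sd

    def scale_target(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean[0]) / self.sd[0]

    def unscale_mean(self, y: np.ndarray) -> np.ndarray:
        return y * self.sd[0] + self.mean[0]

    def unscale_sd(self, sd: np.ndarray) -> np.ndarray:
        return sd * self.sd[0]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ChannelScaler)
            and np.array_equal(self.mean, other.mean)
            and np.array_equal(self.sd, other.sd)
        )


@dataclass
class FeatureWindows:
    """Supervised tensors for the forecaster.

    ``inputs`` has shape ``(n_windows, L, 4)`` in raw physical units
    (channels ordered as :data:`CHANNEL_NAMES`); ``targets`` is the glucose
    channel at ``window end + PH`` in mg/dl and is never scaled — scaling is
    applied to model inputs at train/predict time via ``scaler``.
    ``target_index`` maps each window to the grid index of its target.
    """

    inputs: np.ndarray
    targets: np.ndarray
    target_index: np.ndarray
    L: int
    PH: int
    glucose_channel: str
    scaler: ChannelScaler | None = None
    source_fingerprint: tuple | None = None

    @property
    def n_windows(self) -> int:
        return len(self.targets)

    def with_scaler(self, scaler: ChannelScaler) -> "FeatureWindows":
        return replace(self, scaler=scaler)

    def scaled_inputs(self) -> np.ndarray:
        if self.scaler is None:
            raise ValueError("no scaler attached; fit or provide one first")
        return self.scaler.transform(self.inputs)

    def last_glucose(self) -> np.ndarray:
        """Unscaled glucose at each window's final history index (persistence input)."""
        return self.inputs[:, -1, 0]


def feature_channels(
    series: PatientSeries,
    glucose_channel: str = "raw",
    smoothed: np.ndarray | None = None,
    carb_params: CarbParams | None = None,
    event_mode: str = "replace",
) -> np.ndarray:
    """Stack the four model channels over the grid; shape ``(n_index, 4)``.

    ``glucose_channel`` selects raw CGM or a caller-supplied smoothed series
    (the smoother is run elsewhere so train/test files stay independent).
    """
    if glucose_channel == "raw":
        glucose = series.cgm
    elif glucose_channel == "smoothed":
        if smoothed is None:
            raise ValueError("glucose_channel='smoothed' requires the smoothed array")
        glucose = np.asarray(smoothed, dtype=float)
    else:
        raise ValueError(f"unknown glucose channel {glucose_channel!r}")
    n = series.n_index
    return np.column_stack(
        [
            glucose,
            effective_carbs(series.meal_events, n, carb_params, mode=event_mode),
            effective_insulin(series.bolus_events, n, mode=event_mode),
            step_feature(series.steps, n),
        ]
    )


def build_windows(
    series: PatientSeries,
    glucose_channel: str = "raw",
    L: int = 24,
    PH: int = 6,
    scaler: ChannelScaler | None = None,
    smoothed: np.ndarray | None = None,
    carb_params: CarbParams | None = None,
    event_mode: str = "replace",
) -> FeatureWindows:
    """Assemble chronological supervised windows.

    One window is emitted per grid index ``t`` where glucose is defined on
    every index of ``[t-L+1, t]`` and at the target index ``t+PH``.  A slot
    counts as defined only where the sensor actually reported a value: the
    smoothed channel interpolates dropout gaps, but interpolated slots are
    not prior data points, so windows and targets are still restricted to
    observed-CGM support (keeping raw and smoothed configurations
    comparable).  When ``scaler`` is None a fresh per-channel z-score scaler
    is fitted on the emitted windows (training usage); otherwise the
    provided (train-fitted) scaler is attached unchanged.
    """
    if L < 1 or PH < 1:
        raise ValueError("L and PH must be >= 1")
    channels = feature_channels(series, glucose_channel, smoothed, carb_params, event_mode)
    glucose = channels[:, 0]
    n = series.n_index
    ok = np.isfinite(glucose) & np.isfinite(series.cgm)
    # history validity: all of [t-L+1, t] observed
    valid_hist = np.convolve(ok.astype(int), np.ones(L, dtype=int), mode="valid") == L
    ts = []
    for t in range(L - 1, n):
        if valid_hist[t - L + 1] and t + PH < n and ok[t + PH]:
            ts.append(t)
    ts_arr = np.asarray(ts, dtype=int)
    if len(ts_arr):
        inputs = np.stack([channels[t - L + 1 : t + 1] for t in ts_arr])
        targets = glucose[ts_arr + PH]
    else:
        inputs = np.empty((0, L, len(CHANNEL_NAMES)))
        targets = np.empty(0)
    windows = FeatureWindows(
        inputs=inputs,
        targets=targets,
        target_index=ts_arr + PH,
        L=L,
        PH=PH,
        glucose_channel=glucose_channel,
        scaler=scaler,
        source_fingerprint=series.fingerprint(),
    )
    if scaler is None and len(ts_arr):
        windows.scaler = ChannelScaler.fit(inputs)
    return windows
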