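"""Seeded synthetic type-1-diabetes patient records with known ground truth.

The real OhioT1DM recordings sit behind a data-use agreement, so every
downstream stage is exercised against simulated records that mimic their
structure: a uniform 5-minute CGM grid with gaps, sparse fingerstick
readings, discrete meal and bolus events, 5-minute step aggregates, and
injected CGM sensor faults (dropouts, spikes, PISA attenuation).

The glucoregulatory dynamics are a deliberately minimal discrete-time model
driven by the same input kinetics the forecaster's feature channels encode
(effective carbohydrate, effective bolus insulin, weighted steps):

    G[k+1] = G[k] + g_c·C_eff[k] − g_i·I_eff[k] − g_s·S_avg[k]
                  + λ·(G_basal − G[k]) + N(0, σ_p²),   clamped to [40, 400]

The CGM channel observes the truth with one grid index of sensor lag (a
stand-in for the blood-to-interstitial diffusion delay) plus white noise;
fingersticks observe the truth with small noise at a few daytime indices.
No physiological fidelity beyond this is claimed — the point is a testbed
whose ground truth is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .data_model import SLOTS_PER_DAY, PatientSeries
from .features import effective_carbs, effective_insulin, step_feature

BG_MIN, BG_MAX = 40.0, 400.0


@dataclass(frozen=True)
class FaultSpec:
    """Rates and shapes of injected CGM sensor faults (per day of data)."""

    dropout_rate: float = 0.5
    dropout_length: tuple[int, int] = (3, 12)
    spike_rate: float = 1.0
    spike_magnitude: tuple[float, float] = (30.0, 80.0)
    pisa_rate: float = 0.5
    pisa_depth: tuple[float, float] = (0.2, 0.5)
    pisa_length: tuple[int, int] = (4, 12)

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "spike_rate", "pisa_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated patient."""

    seed: int = 0
    days: int = 7
    basal_glucose: float = 120.0  # mg/dl
    carb_gain: float = 0.5  # mg/dl per gram effective carbs
    insulin_gain: float = 3.0  # mg/dl per effective insulin unit
    activity_gain: float = 0.002  # mg/dl per weighted-step unit
    mean_reversion: float = 0.05  # per-index pull toward basal_glucose
    process_noise_sd: float = 1.0  # mg/dl
    sensor_noise_sd: float = 5.0  # mg/dl
    sensor_lag: int = 1  # grid indices
    fault_spec: FaultSpec = field(default_factory=FaultSpec)
    meals_per_day: tuple[int, int] = (3, 5)
    carbs_per_meal: tuple[float, float] = (20.0, 100.0)
    insulin_to_carb_ratio: float = 0.1  # units per gram
    fingersticks_per_day: int = 4
    patient_id: str = "sim"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for name in (
            "carb_gain",
            "insulin_gain",
            "activity_gain",
            "process_noise_sd",
            "sensor_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _daytime_indices(day: int, rng: np.random.Generator, count: int, lo_h=7, hi_h=22) -> np.ndarray:
    lo = day * SLOTS_PER_DAY + lo_h * 12
    hi = day * SLOTS_PER_DAY + hi_h * 12
    return rng.choice(np.arange(lo, hi), size=count, replace=False)


def _sample_events(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Draw meal/bolus schedules, step-count trace and fingerstick slots."""
    meals: list[tuple[int, float]] = []
    boluses: list[tuple[int, float]] = []
    steps = np.zeros(n)
    fs_slots: list[int] = []
    for day in range(config.days):
        n_meals = int(rng.integers(config.meals_per_day[0], config.meals_per_day[1] + 1))
        # meals spread over breakfast..dinner hours, jittered
        hours = np.sort(rng.uniform(7, 21, size=n_meals))
        for h in hours:
            idx = day * SLOTS_PER_DAY + int(h * 12)
            if idx >= n:
                continue
            grams = float(rng.uniform(*config.carbs_per_meal))
            meals.append((idx, grams))
            boluses.append((idx, grams * config.insulin_to_carb_ratio))
        # walking bouts: a few per day, 10-60 min, ~100-500 steps per 5 min
        for _ in range(int(rng.integers(2, 7))):
            start = day * SLOTS_PER_DAY + int(rng.uniform(8, 22) * 12)
            length = int(rng.integers(2, 13))
            level = max(0.0, rng.normal(300, 120))
            steps[start : min(start + length, n)] += rng.poisson(level, size=min(length, n - start))
        fs_slots.extend(_daytime_indices(day, rng, config.fingersticks_per_day).tolist())
    # de-duplicate meal slots (two meals in one slot are merged)
    merged: dict[int, float] = {}
    for idx, grams in meals:
        merged[idx] = merged.get(idx, 0.0) + grams
    meals = sorted(merged.items())
    merged_b: dict[int, float] = {}
    for idx, units in boluses:
        merged_b[idx] = merged_b.get(idx, 0.0) + units
    boluses = sorted(merged_b.items())
    return meals, boluses, steps, sorted(set(fs_slots))


def generate_patient(config: SimulationConfig) -> PatientSeries:
    """Simulate one patient record (faults included per ``config.fault_spec``).

    Identical config (seed included) yields a bit-identical record.
    """
    rng = np.random.default_rng(config.seed)
    n = config.days * SLOTS_PER_DAY
    meals, boluses, steps, fs_slots = _sample_events(config, rng, n)

    c_eff = effective_carbs(meals, n)
    i_eff = effective_insulin(boluses, n)
    s_avg = step_feature(steps, n)

    truth = np.empty(n)
    truth[0] = config.basal_glucose
    process_noise = rng.normal(0.0, config.process_noise_sd, size=n)
    for k in range(n - 1):
        drift = (
            config.carb_gain * c_eff[k]
            - config.insulin_gain * i_eff[k]
            - config.activity_gain * s_avg[k]
            + config.mean_reversion * (config.basal_glucose - truth[k])
        )
        truth[k + 1] = np.clip(truth[k] + drift + process_noise[k], BG_MIN, BG_MAX)

    lag = config.sensor_lag
    lagged = np.concatenate([np.full(lag, truth[0]), truth[: n - lag]]) if lag else truth
    cgm = np.clip(lagged + rng.normal(0.0, config.sensor_noise_sd, size=n), BG_MIN, BG_MAX)

    fingerstick = [
        (int(i), float(np.clip(truth[i] + rng.normal(0.0, 2.0), BG_MIN, BG_MAX)))
        for i in fs_slots
    ]

    series = PatientSeries(
        patient_id=config.patient_id,
        gender="unknown",
        grid_start=datetime(2024, 1, 1),
        n_index=n,
        cgm=cgm,
        fingerstick=fingerstick,
        bolus_events=[(i, float(v)) for i, v in boluses],
        meal_events=[(i, float(v)) for i, v in meals],
        steps=steps,
        truth_bg=truth,
    )
    fault_seed = int(rng.integers(0, 2**31 - 1))
    return inject_faults(series, config.fault_spec, seed=fault_seed)


# --- fault primitives (used directly by inject_faults and by tests) ---------


def apply_dropout(cgm: np.ndarray, start: int, length: int) -> None:
    cgm[start : start + length] = np.nan


def apply_spike(cgm: np.ndarray, index: int, magnitude: float) -> None:
    if np.isfinite(cgm[index]):
        cgm[index] = max(BG_MIN, min(BG_MAX, cgm[index] + magnitude))


def apply_pisa(cgm: np.ndarray, start: int, length: int, depth: float) -> None:
    """Pressure-induced attenuation: multiplicative under-reading by (1 - depth)."""
    span = slice(start, start + length)
    cgm[span] = np.where(np.isfinite(cgm[span]), cgm[span] * (1.0 - depth), cgm[span])


def inject_faults(series: PatientSeries, spec: FaultSpec, seed: int) -> PatientSeries:
    """Return a copy of ``series`` with sensor faults injected into the CGM channel.

    Fault counts are Poisson with mean ``rate * days``; positions are uniform
    over the grid.  ``truth_bg`` and all non-CGM channels are untouched.  A
    log of the injected faults is attached as ``fault_log``.
    """
    rng = np.random.default_rng(seed)
    out = series.copy()
    cgm = out.cgm
    days = series.n_index / SLOTS_PER_DAY
    log: list[dict] = []
    for _ in range(rng.poisson(spec.dropout_rate * days)):
        length = int(rng.integers(spec.dropout_length[0], spec.dropout_length[1] + 1))
        start = int(rng.integers(0, max(1, series.n_index - length)))
        apply_dropout(cgm, start, length)
        log.append({"kind": "dropout", "start": start, "length": length})
    for _ in range(rng.poisson(spec.spike_rate * days)):
        index = int(rng.integers(0, series.n_index))
        magnitude = float(rng.uniform(*spec.spike_magnitude)) * (1 if rng.random() < 0.5 else -1)
        apply_spike(cgm, index, magnitude)
        log.append({"kind": "spike", "start": index, "length": 1, "magnitude": magnitude})
    for _ in range(rng.poisson(spec.pisa_rate * days)):
        length = int(rng.integers(spec.pisa_length[0], spec.pisa_length[1] + 1))
        start = int(rng.integers(0, max(1, series.n_index - length)))
        depth = float(rng.uniform(*spec.pisa_depth))
        apply_pisa(cgm, start, length, depth)
        log.append({"kind": "pisa", "start": start, "length": length, "depth": depth})
    out.fault_log = series.fault_log + log
    return out


def no_fault_config(**overrides) -> SimulationConfig:
    """A SimulationConfig with all fault rates zeroed (convenience for tests)."""
    spec = FaultSpec(dropout_rate=0.0, spike_rate=0.0, pisa_rate=0.0)
    return replace(SimulationConfig(fault_spec=spec), **overrides)
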