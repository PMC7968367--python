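# Methods

`cgmforecast` implements a blood-glucose forecasting pipeline for type-1
diabetes: continuous glucose monitor (CGM) traces are corrected for sensor
error with a Kalman smoother, combined with physiologically motivated input
features, and fed to a stacked-LSTM network that outputs a predictive
Gaussian for the glucose level 30 or 60 minutes ahead. A seeded simulator
provides ground-truth-bearing patient records so the whole pipeline is
testable without restricted clinical data.

## Data model

A patient record lives on a uniform 5-minute grid (288 slots/day). Off-grid
event timestamps map to slot `floor((t - grid_start)/5 min)` — half-open
bins, deterministic and order-preserving. Timestamps are timezone-naive
local clock times. Dense channels (CGM, band channels) keep missingness as
NaN end-to-end; nothing at the I/O layer imputes. Missing step slots are
encoded as 0, because the step feature needs a dense series and the absence
of a fitness-band record most plausibly means no recorded steps. Basal
insulin, heart rate, GSR and temperatures are parsed and stored but unused
by the default pipeline (the four-channel feature set below was selected as
optimal on real data); retaining them enables ablations.

## Feature crafting

Four channels per grid index feed the forecaster:

* **Glucose** `G` — raw CGM or the Kalman-smoothed posterior mean (mg/dl).
* **Effective carbohydrate** `C_eff` (grams): after a meal of `C_meal` grams
  at index `t_meal`, absorption is ignored for the first 15 min (3 indices),
  rises linearly at `β_inc = 0.111` of the meal per index for the next 9
  indices (so the peak reaches `9 × 0.111 ≈ 99.9 %` of the meal at the
  60-minute mark and never exceeds it), then decays as
  `C_meal · (1 − d · β_dec)` with `β_dec = 0.028` per index on a decay clock
  `d` that starts at the peak — after 36 decay indices (3 h) the remainder
  clamps to zero. The rise multiplies the elapsed time *past the lag*
  (`e − 3`, not raw `e`): multiplying raw elapsed time would overshoot the
  meal (12·0.111 = 1.33), and starting the decay clock at the meal instead
  of the peak would produce a discontinuity there. A new meal replaces the
  tracked `(t_meal, C_meal)` pair; an additive-superposition mode is
  available for sensitivity analysis.
* **Effective bolus insulin** `I_eff` (units): linear insulin-on-board decay
  `max(0, I_bolus − e · R_insulin)` with `R_insulin = 5 × 0.014 = 0.07`
  units/index — the 5-minute aggregate of a 0.014 min⁻¹ population
  absorption rate (the 67 %/33 % slow/fast pathway average). No absorption
  delay is modelled. A new bolus replaces the tracked pair.
* **Weighted step count** `S_avg`: a triangular trailing average over the
  last 10 indices (50 min), `S_avg(t) = (1/10) Σ_{i=0}^{9} (10−i)·steps(t−i)`,
  emphasizing the most recent activity; a constant step rate `s` maps to
  `5.5·s`.

Supervised windows pair `L = 24` consecutive indices (2 h) of the four
channels with the glucose value `PH` indices past the window end (6 for
30 min, 12 for 60 min). A slot counts as observed only where the sensor
actually reported: the smoother interpolates dropout gaps, but interpolated
slots are not prior data points, so windows and targets are restricted to
observed-CGM support in both channel configurations — this keeps the raw
and smoothed arms scoring the same target set. Inputs are standardized
per channel with a scaler fitted on training windows only; targets stay in
mg/dl and predictions are inverse-transformed before any RMSE.

## Sensor-fault correction

The CGM trace is modelled as a local linear trend observed in noise:
state `x = [glucose, rate]`, `Φ = [[1,1],[0,1]]`, `H = [1,0]`,
white-noise-jerk process covariance `Q = q·[[1/3,1/2],[1/2,1]]`, measurement
variance `R`. A forward Kalman filter (time update everywhere, measure
update only at observed slots) followed by a Rauch–Tung–Striebel backward
pass yields a posterior mean and variance at every index; gaps receive
interpolated means with inflated variance. Smoothing is applied per data
file — training and test files of a patient are smoothed separately so no
test information leaks into training inputs.

Defaults: `R = 25 (mg/dl)²` (a 5 mg/dl sensor noise sd) and `q = 10`.
The process scale matches the physiological rate-of-change of glucose at
5-minute resolution (rate increments of a few mg/dl per index; the
simulator's truth has second-difference variance ≈ 11 (mg/dl)²). Behaviour
is insensitive across `q ≈ 2–20`; a much smaller `q` over-smooths and makes
the "corrected" trace *worse* than raw against ground truth. Initialization
is diffuse at the first observation: `x0 = [y_first, 0]`,
`P0 = diag(1e4, 1e2)`. Numerical notes: the filter uses the standard
innovation form of the measure update and the smoother the standard RTS
gain `C_k = P̂_k Φᵀ P̄⁻¹_{k+1}`; the backward pass solves rather than
inverts, and a singular predicted covariance is reported with its index.
Correctness is pinned by an independent oracle: on small instances the
smoothed means must match a dense batch weighted-least-squares solve of the
same joint Gaussian to 1e-8 relative.

## Forecaster

Architecture: input `(L × 4)` → LSTM(128, full sequence) → dropout(0.2) →
LSTM(128, final vector) → dense 512 (ReLU) → dense 128 (ReLU) → output
head. The default head emits two numbers — a mean and a log-variance whose
exponential is the predictive variance — because the training loss is the
Gaussian negative log-likelihood and the forecasts carry ±1 sd bands. A
literal single exponential-activated output neuron is available
(`single_exponential`) with one learned global variance; a single
exponential output alone cannot support a per-forecast NLL, which is why it
is not the default. Forecasts are direct (single-shot) at `t + PH`, not
recursive rollouts. The single-layer variant (`n_recurrent_layers = 1`)
supports stacked-vs-single comparisons.

Because no deep-learning framework is a dependency, the network is
implemented directly in NumPy (float32): fused-gate LSTM layers with
hand-derived backward passes, inverted dropout, dense layers, and Adam with
global-norm gradient clipping at 5 (a stability guard for the exponential
variance head). Gate layout is `[input, forget, candidate, output]` acting
on `[h_prev, x]`, forget bias initialized to 1, Glorot-uniform weights. A
finite-difference gradient check on a tiny network is part of the test
suite.

Training: chronological 80/20 train/validation split (the validation set is
the most recent tail — no shuffling across the boundary), Adam at 1e-3,
batches of 128 (batch order shuffled within the training set from a seeded
generator), up to 6000 epochs with early stopping after 128 epochs without
validation improvement, restoring the best epoch's parameters. One seed in
`ModelConfig` controls weight init, dropout masks and batch order; two runs
with the same seed and data are bit-identical in single-threaded use.
Reported NLL is in mg/dl units (the scaled-space NLL plus `log` of the
target scale) so it is recomputable from the returned predictive
distributions.

## Synthetic patients

The simulator emulates the structure of real CGM study data: a 5-minute
grid, 3–5 meals/day of 20–100 g at daytime hours, a bolus at 0.1 U/g with
each meal, walking bouts yielding 5-minute step aggregates, 4 fingersticks
per day (truth + 2 mg/dl noise), and CGM sensor faults. The true glucose
follows a discrete mean-reverting model driven by the same input kinetics
the features encode:

    G[k+1] = G[k] + 0.5·C_eff[k] − 3.0·I_eff[k] − 0.002·S_avg[k]
                  + 0.05·(120 − G[k]) + N(0, 1),  clamped to [40, 400] mg/dl

The CGM observes the truth with one grid index of lag (a stand-in for the
blood-to-interstitial diffusion delay) plus N(0, 5²) noise. Faults are
injected at Poisson rates per day: dropouts (0.5/day, 3–12 slots), isolated
additive spikes (1/day, ±30–80 mg/dl), and pressure-induced sensor
attenuation (0.5/day, multiplicative under-reading of 20–50 % over 4–12
slots) — plausible magnitudes for real CGM artifacts; every injected fault
is logged. Deliberately *not* modelled: insulin/meal physiology beyond
these first-order kinetics (no Bergman/UVA-Padova compartments), circadian
hormones, exercise intensity, calibration drift. Consequently, passing
tests demonstrate pipeline correctness and directional behaviour under a
known-truth generator, not clinical accuracy on real patients.

## Evaluation

Two RMSE criteria: **sensor accuracy** pairs each fingerstick with the raw
or smoothed CGM value in the same grid slot (fingersticks in CGM gaps are
dropped and counted); **forecast accuracy** is the RMSE of predictive means
at horizon PH against a chosen reference — raw CGM, smoothed CGM, or (on
synthetic data only) the simulator truth, which substitutes for the sparse
fingerstick ground truth available in real data. The persistence baseline
predicts each window's last observed glucose; its error on a pure ramp of
slope `m` per index is exactly `|m|·PH`. `evaluate` refuses to score a
model on its own training series.

## Desk-scale experiment profile

The shipped multi-seed studies (`cgmforecast.experiments`) train a stacked
two-layer LSTM with 32 hidden units and a 64/32 dense head for up to 200
epochs (early-stopping patience 25) on 30 simulated days, evaluating on 3
held-out days — sizes chosen so a full paired 5-seed, two-channel study
runs in minutes on one CPU core while keeping the architecture, loss,
split discipline and all other defaults identical to the full-width model.
Channel comparisons are paired: both arms share the simulated records and
the weight-init seed, differing only in the glucose channel.

Observed behaviour under these conditions: the smoother beats the raw
sensor against truth on essentially every seed; the LSTM beats persistence
on every seed; the *forecast*-level smoothed-vs-raw input comparison scored
against simulator truth is a coin flip with a slight edge to raw inputs. The
last point is expected on reflection: a flexible sequence model can filter
raw inputs itself, conditioned on the forecasting objective, so acausal
preprocessing adds little against a ground-truth reference — its large
apparent gains arise when predictions are scored against the smoothed trace
itself.

## Known limitations

* The simulator's volatility is higher than typical real CGM traces, so
  absolute RMSEs are not comparable to clinical numbers.
* The smoother state-space model is fixed (no adaptive noise estimation,
  no outlier-robust variant, no calibration-drift state).
* Per-patient models are fully independent; no transfer across patients.
* The NumPy trainer is CPU-bound; the full-width default (128 hidden,
  512/128 dense) trains slowly compared to GPU frameworks.
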