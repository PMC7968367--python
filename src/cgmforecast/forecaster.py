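"""Stacked-LSTM probabilistic glucose forecaster.

Architecture (per the two-layer stacked recurrent design): an ``L x 4``
history window feeds an LSTM that returns its full hidden sequence, a
dropout layer, a second LSTM whose final hidden vector feeds a dense head
(512 -> 128 units, ReLU) ending in a distribution head.  The default
``gaussian_two_param`` head emits a predictive mean and a log-variance
(exponentiated to a positive variance), trained with the Gaussian negative
log-likelihood; ``single_exponential`` is the literal single
exponential-activated output neuron with one learned global variance.

Training follows time-series discipline: a chronological 80/20
train/validation split, Adam, mini-batches of 128 windows, and early
stopping on validation NLL with parameter restoration from the best epoch.
Forecasts are direct (single-shot) at horizon ``PH`` — no recursive rollout.

The public surface is statsmodels-shaped: :class:`GlucoseForecaster` is the
model, ``fit()`` returns :class:`ForecastResults` which carries the learned
parameters, the training log and ``predict``/``summary``.  Thin functional
wrappers :func:`build_model`, :func:`train` and :func:`predict` expose the
same steps pipeline-style.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from ._nn import DTYPE, Adam, DenseLayer, DropoutLayer, LSTMLayer
from .features import FeatureWindows

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the forecaster."""

    n_recurrent_layers: int = 2  # 2 = stacked; 1 = single-LSTM variant
    hidden_units: int = 128
    recurrent_cell: str = "lstm"
    dropout_rate: float = 0.2  # applied after the first LSTM layer
    dense_sizes: tuple[int, ...] = (512, 128)
    dense_activations: tuple[str, ...] = ("relu", "relu")
    output_head: str = "gaussian_two_param"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 6000
    patience: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recurrent_cell != "lstm":
            raise ValueError(f"unsupported recurrent cell {self.recurrent_cell!r}")
        if self.output_head not in ("gaussian_two_param", "single_exponential"):
            raise ValueError(f"unsupported output head {self.output_head!r}")
        if self.hidden_units < 1 or self.n_recurrent_layers < 1:
            raise ValueError("hidden_units and n_recurrent_layers must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.dense_sizes) != len(self.dense_activations):
            raise ValueError("dense_sizes and dense_activations must align")


class Network:
    """The assembled layers; internal but importable for inspection/tests."""

    def __init__(self, config: ModelConfig, L: int, n_channels: int):
        self.config = config
        self.L = L
        self.n_channels = n_channels
        rng = np.random.default_rng(config.seed)
        self.lstm_layers: list[LSTMLayer] = []
        in_dim = n_channels
        for i in range(config.n_recurrent_layers):
            self.lstm_layers.append(LSTMLayer(in_dim, config.hidden_units, rng, f"lstm{i}"))
            in_dim = config.hidden_units
        self.dropout = DropoutLayer(config.dropout_rate)
        self.dense_layers: list[DenseLayer] = []
        for i, (units, act) in enumerate(zip(config.dense_sizes, config.dense_activations)):
            self.dense_layers.append(DenseLayer(in_dim, units, act, rng, f"dense{i}"))
            in_dim = units
        if config.output_head == "gaussian_two_param":
            self.head = DenseLayer(in_dim, 2, "linear", rng, "head")
            self.global_logvar = None
        else:
            self.head = DenseLayer(in_dim, 1, "exponential", rng, "head")
            self.global_logvar = np.zeros(1, dtype=DTYPE)
        self.d_global_logvar = np.zeros(1, dtype=DTYPE)

    # -- parameter plumbing ------------------------------------------------
    def _layers(self):
        return [*self.lstm_layers, *self.dense_layers, self.head]

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        if self.global_logvar is not None:
            out.append(("global_logvar", self.global_logvar))
        return out

    def grads(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads())
        if self.global_logvar is not None:
            out.append(("global_logvar", self.d_global_logvar))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.params())

    def get_state(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p in self.params()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.params():
            p[...] = state[name]

    # -- forward / backward ------------------------------------------------
    def forward(
        self,
        X: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
        keep_cache: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scaled-space predictive (mean, log-variance) per window."""
        if X.shape[1:] != (self.L, self.n_channels):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match model input ({self.L}, {self.n_channels})"
            )
        h = X.astype(DTYPE, copy=False)
        for i, lstm in enumerate(self.lstm_layers):
            h = lstm.forward(h, keep_cache=keep_cache)
            if i == 0 and len(self.lstm_layers) > 1:
                h = self.dropout.forward(h, dropout_rng)
        vec = h[:, -1]  # final hidden vector of the last LSTM
        for dense in self.dense_layers:
            vec = dense.forward(vec, keep_cache=keep_cache)
        out = self.head.forward(vec, keep_cache=keep_cache)
        if self.config.output_head == "gaussian_two_param":
            mu, logvar = out[:, 0], np.clip(out[:, 1], -12.0, 12.0)
        else:
            mu = out[:, 0]
            logvar = np.full_like(mu, self.global_logvar[0])
        return mu, logvar

    def backward(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        if self.config.output_head == "gaussian_two_param":
            dout = np.stack([dmu, dlogvar], axis=1).astype(DTYPE)
        else:
            dout = dmu[:, None].astype(DTYPE)
            self.d_global_logvar[...] = dlogvar.sum()
        d = self.head.backward(dout)
        for dense in reversed(self.dense_layers):
            d = dense.backward(d)
        B = len(dmu)
        dH_seq = np.zeros((B, self.L, self.config.hidden_units), dtype=DTYPE)
        dH_seq[:, -1] = d
        for i in range(len(self.lstm_layers) - 1, -1, -1):
            if i == 1:
                dH_seq = self.lstm_layers[i].backward(dH_seq)
                dH_seq = self.dropout.backward(dH_seq)
            else:
                dH_seq = self.lstm_layers[i].backward(dH_seq)


@dataclass
class ForecastResult:
    """Per-window predictive distribution in physical units (mg/dl)."""

    mean: np.ndarray
    sd: np.ndarray
    target_index: np.ndarray


@dataclass
class ForecastResults:
    """Fitted-forecaster results object (parameters, diagnostics, predict)."""

    network: Network
    config: ModelConfig
    scaler: object
    training_log: list[dict]
    best_epoch: int
    stopped_epoch: int
    L: int
    PH: int
    glucose_channel: str
    train_fingerprint: tuple | None = None
    split_fraction: float = 0.8

    @property
    def best_validation_nll(self) -> float:
        return self.training_log[self.best_epoch - 1]["val_nll"]

    def predict(self, windows: FeatureWindows) -> ForecastResult:
        """Direct forecast at ``window end + PH`` for each window.

        Windows must have been built with the same ``L`` and channel layout;
        they are transformed with the *training* scaler (a conflicting
        scaler attached to ``windows`` is an error).
        """
        if windows.L != self.L:
            raise ValueError(f"windows have L={windows.L}, model expects L={self.L}")
        if windows.scaler is not None and windows.scaler != self.scaler:
            raise ValueError("windows carry a different scaler than the training scaler")
        X = self.scaler.transform(windows.inputs)
        mus, logvars = [], []
        for start in range(0, len(X), 512):
            mu, logvar = self.network.forward(X[start : start + 512], keep_cache=False)
            mus.append(mu)
            logvars.append(logvar)
        mu = np.concatenate(mus) if mus else np.empty(0)
        logvar = np.concatenate(logvars) if logvars else np.empty(0)
        sd_scaled = np.exp(0.5 * logvar.astype(np.float64))
        return ForecastResult(
            mean=self.scaler.unscale_mean(mu.astype(np.float64)),
            sd=self.scaler.unscale_sd(sd_scaled),
            target_index=windows.target_index.copy(),
        )

    def nll(self, windows: FeatureWindows) -> float:
        """Mean Gaussian NLL of ``windows.targets`` (mg/dl units)."""
        res = self.predict(windows)
        var = res.sd**2
        return float(np.mean(0.5 * (LOG_2PI + np.log(var) + (windows.targets - res.mean) ** 2 / var)))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Glucose forecaster (stacked LSTM)" if cfg.n_recurrent_layers > 1 else "Glucose forecaster (single LSTM)",
            "=" * 48,
            f"recurrent layers     {cfg.n_recurrent_layers} x LSTM({cfg.hidden_units})",
            f"dense head           {cfg.dense_sizes} {cfg.dense_activations}",
            f"output head          {cfg.output_head}",
            f"parameters           {self.network.n_parameters}",
            f"history / horizon    L={self.L} indices, PH={self.PH} indices",
            f"glucose channel      {self.glucose_channel}",
            f"epochs run           {self.stopped_epoch} (best: {self.best_epoch}, patience {cfg.patience})",
            f"best validation NLL  {self.best_validation_nll:.4f}",
        ]
        return "\n".join(lines)


class GlucoseForecaster:
    """Model object: feature windows in, :class:`ForecastResults` out of ``fit``."""

    def __init__(self, windows: FeatureWindows, config: ModelConfig | None = None):
        if windows.n_windows < 2:
            raise ValueError("need at least 2 windows to fit")
        self.windows = windows
        self.config = config or ModelConfig()

    @classmethod
    def from_series(cls, series, config=None, glucose_channel="raw", L=24, PH=6, smoothed=None):
        from .features import build_windows

        return cls(build_windows(series, glucose_channel, L, PH, smoothed=smoothed), config)

    def fit(self, split_fraction: float = 0.8, verbose: bool = False) -> ForecastResults:
        windows = self.windows
        cfg = self.config
        network = Network(cfg, windows.L, windows.inputs.shape[-1])
        return _train_network(network, windows, cfg, split_fraction, verbose)


def _train_network(
    network: Network,
    windows: FeatureWindows,
    cfg: ModelConfig,
    split_fraction: float = 0.8,
    verbose: bool = False,
) -> ForecastResults:
    scaler = windows.scaler
    if scaler is None:
        from .features import ChannelScaler

        scaler = ChannelScaler.fit(windows.inputs)
    n = windows.n_windows
    n_train = max(1, int(n * split_fraction))
    if n_train >= n:
        n_train = n - 1
    X = scaler.transform(windows.inputs).astype(DTYPE)
    y = scaler.scale_target(windows.targets).astype(DTYPE)
    # chronological split: validation is the most recent tail
    X_tr, y_tr = X[:n_train], y[:n_train]
    X_va, y_va = X[n_train:], y[n_train:]
    log_s0 = math.log(float(scaler.sd[0]))  # reported NLL is in mg/dl units

    opt = Adam(lr=cfg.learning_rate)
    rng_order = np.random.default_rng((cfg.seed, 1))
    rng_drop = np.random.default_rng((cfg.seed, 2))
    training_log: list[dict] = []
    best_val = math.inf
    best_state = network.get_state()
    best_epoch = 0
    since_improved = 0
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng_order.permutation(n_train)
        total_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            mu, logvar = network.forward(xb, dropout_rng=rng_drop)
            inv_var = np.exp(-logvar.astype(np.float64))
            resid = mu.astype(np.float64) - yb
            nll = 0.5 * (LOG_2PI + logvar + resid**2 * inv_var) + log_s0
            batch_loss = float(nll.mean())
            if not math.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(|resid| max {np.abs(resid).max():.3g}, logvar range "
                    f"[{logvar.min():.3g}, {logvar.max():.3g}])"
                )
            total_loss += batch_loss * len(idx)
            B = len(idx)
            dmu = (resid * inv_var / B).astype(DTYPE)
            dlogvar = (0.5 * (1.0 - resid**2 * inv_var) / B).astype(DTYPE)
            network.backward(dmu, dlogvar)
            opt.step(network.params(), network.grads())
        train_nll = total_loss / n_train
        val_nll = _eval_nll(network, X_va, y_va, log_s0)
        training_log.append({"epoch": epoch, "train_nll": train_nll, "val_nll": val_nll})
        if verbose:
            print(f"epoch {epoch:4d}  train {train_nll:.4f}  val {val_nll:.4f}")
        if val_nll < best_val:
            best_val = val_nll
            best_state = network.get_state()
            best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= cfg.patience:
                break
    network.set_state(best_state)
    return ForecastResults(
        network=network,
        config=cfg,
        scaler=copy.deepcopy(scaler),
        training_log=training_log,
        best_epoch=best_epoch,
        stopped_epoch=epoch,
        L=windows.L,
        PH=windows.PH,
        glucose_channel=windows.glucose_channel,
        train_fingerprint=windows.source_fingerprint,
        split_fraction=split_fraction,
    )


def _eval_nll(network: Network, X: np.ndarray, y: np.ndarray, log_s0: float) -> float:
    total, count = 0.0, 0
    for start in range(0, len(X), 512):
        xb, yb = X[start : start + 512], y[start : start + 512]
        mu, logvar = network.forward(xb, keep_cache=False)
        resid = mu.astype(np.float64) - yb
        nll = 0.5 * (LOG_2PI + logvar + resid**2 * np.exp(-logvar.astype(np.float64))) + log_s0
        total += float(nll.sum())
        count += len(xb)
    return total / max(count, 1)


# -- pipeline-style wrappers ----------------------------------------------


def build_model(config: ModelConfig, L: int = 24, n_channels: int = 4) -> Network:
    """Construct the untrained network for the given hyperparameters."""
    return Network(config, L, n_channels)


def train(model: Network, windows: FeatureWindows, split_fraction: float = 0.8) -> ForecastResults:
    """Train an untrained network on supervised windows (chronological split)."""
    if windows.n_windows < 2:
        raise ValueError("need at least 2 windows to train")
    return _train_network(model, windows, model.config, split_fraction)


def predict(trained: ForecastResults, windows: FeatureWindows) -> ForecastResult:
    """Apply a fitted forecaster to windows (see :meth:`ForecastResults.predict`)."""
    return trained.predict(windows)
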