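import dataclasses
from datetime import datetime

import numpy as np
import pytest

from cgmforecast._nn import DTYPE
from cgmforecast.data_model import PatientSeries
from cgmforecast.features import build_windows
from cgmforecast.forecaster import (
    GlucoseForecaster,
    ModelConfig,
    Network,
    build_model,
    predict,
    train,
)


def _ramp_series(n=260, slope=0.5, start=100.0, meals=()):
    return PatientSeries(
        patient_id="ramp", grid_start=datetime(2024, 1, 1), n_index=n,
        cgm=start + slope * np.arange(n), meal_events=list(meals),
    )


def _slice_windows(windows, sl):
    return dataclasses.replace(
        windows,
        inputs=windows.inputs[sl],
        targets=windows.targets[sl],
        target_index=windows.target_index[sl],
    )


TINY = ModelConfig(
    hidden_units=5, dense_sizes=(8, 4), dense_activations=("relu", "relu"),
    batch_size=32, max_epochs=4, patience=4, seed=3,
)


class TestBuildModel:
    def test_deterministic_initialization(self):
        a = build_model(TINY, L=12)
        b = build_model(TINY, L=12)
        assert a.n_parameters == b.n_parameters
        for (na, pa), (nb, pb) in zip(a.params(), b.params()):
            assert na == nb
            np.testing.assert_array_equal(pa, pb)

    def test_parameter_count_default_architecture(self):
        net = build_model(ModelConfig(), L=24)
        # two LSTM(128) layers + dense 512/128 + 2-unit gaussian head
        lstm1 = (4 + 128) * 512 + 512
        lstm2 = (128 + 128) * 512 + 512
        dense = 128 * 512 + 512 + 512 * 128 + 128
        head = 128 * 2 + 2
        assert net.n_parameters == lstm1 + lstm2 + dense + head

    def test_single_layer_variant(self):
        cfg = dataclasses.replace(TINY, n_recurrent_layers=1)
        net = build_model(cfg, L=12)
        assert len(net.lstm_layers) == 1
        mu, logvar = net.forward(np.zeros((3, 12, 4), dtype=DTYPE))
        assert mu.shape == (3,) and logvar.shape == (3,)

    def test_rejects_wrong_input_shape(self):
        net = build_model(TINY, L=12)
        with pytest.raises(ValueError, match="input shape"):
            net.forward(np.zeros((2, 11, 4), dtype=DTYPE))
        with pytest.raises(ValueError, match="input shape"):
            net.forward(np.zeros((2, 12, 3), dtype=DTYPE))

    @pytest.mark.parametrize("field, value", [
        ("recurrent_cell", "gru"),
        ("output_head", "softmax"),
        ("dropout_rate", 1.0),
        ("patience", 10_000),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(ModelConfig(), **{field: value})


class TestGradients:
    """Analytic backprop against central finite differences on a tiny network."""

    @pytest.mark.parametrize("head", ["gaussian_two_param", "single_exponential"])
    def test_loss_gradient_matches_finite_differences(self, head):
        cfg = ModelConfig(
            hidden_units=3, dense_sizes=(4,), dense_activations=("relu",),
            output_head=head, seed=1, batch_size=4, max_epochs=1, patience=1,
        )
        net = Network(cfg, L=5, n_channels=4)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 5, 4)).astype(DTYPE)
        y = rng.normal(size=4)

        def loss():
            mu, logvar = net.forward(X)
            resid = mu.astype(np.float64) - y
            return float(np.mean(0.5 * (np.log(2 * np.pi) + logvar + resid**2 * np.exp(-logvar.astype(np.float64)))))

        # analytic gradients
        mu, logvar = net.forward(X)
        inv_var = np.exp(-logvar.astype(np.float64))
        resid = mu.astype(np.float64) - y
        B = len(y)
        net.backward(
            (resid * inv_var / B).astype(DTYPE),
            (0.5 * (1.0 - resid**2 * inv_var) / B).astype(DTYPE),
        )
        analytic = {name: g.copy() for name, g in net.grads()}

        eps = 1e-3
        for name, p in net.params():
            flat = p.reshape(-1)
            for j in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                up = loss()
                flat[j] = orig - eps
                down = loss()
                flat[j] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic[name].reshape(-1)[j] == pytest.approx(numeric, rel=2e-2, abs=2e-4), name


@pytest.fixture(scope="module")
def ramp_windows():
    return build_windows(_ramp_series(), L=12, PH=6)


class TestTraining:
    def test_learnability_on_periodic_signal(self):
        n = 300
        series = PatientSeries(
            patient_id="sine", grid_start=datetime(2024, 1, 1), n_index=n,
            cgm=140 + 40 * np.sin(np.arange(n) / 8),
        )
        windows = build_windows(series, L=12, PH=6)
        cfg = dataclasses.replace(TINY, max_epochs=30, patience=30)
        results = train(build_model(cfg, L=12), windows)
        log = results.training_log
        assert results.best_validation_nll < log[0]["val_nll"]
        assert log[-1]["train_nll"] < log[0]["train_nll"]

    def test_fixed_seed_reproduces_training_log(self, ramp_windows):
        r1 = train(build_model(TINY, L=12), ramp_windows)
        r2 = train(build_model(TINY, L=12), ramp_windows)
        assert r1.training_log == r2.training_log
        p1 = r1.predict(ramp_windows)
        p2 = r2.predict(ramp_windows)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        np.testing.assert_array_equal(p1.sd, p2.sd)

    def test_early_stopping_restores_best_epoch(self, ramp_windows):
        cfg = dataclasses.replace(TINY, max_epochs=30, patience=5)
        results = train(build_model(cfg, L=12), ramp_windows)
        vals = [e["val_nll"] for e in results.training_log]
        assert results.best_epoch == int(np.argmin(vals)) + 1
        assert results.best_validation_nll == min(vals)
        assert results.stopped_epoch <= cfg.max_epochs

    def test_reported_validation_nll_matches_forecast_nll(self, ramp_windows):
        """The training loop's validation loss is recomputable from predictions."""
        results = train(build_model(TINY, L=12), ramp_windows)
        n_train = int(ramp_windows.n_windows * 0.8)
        val = _slice_windows(ramp_windows, slice(n_train, None))
        # training restored the best epoch's parameters
        assert results.nll(val) == pytest.approx(results.best_validation_nll, abs=1e-6)

    def test_non_finite_loss_aborts_with_diagnostic(self, ramp_windows):
        bad = dataclasses.replace(
            _slice_windows(ramp_windows, slice(None)), targets=ramp_windows.targets * np.inf
        )
        with pytest.raises((RuntimeError, ValueError)):
            train(build_model(TINY, L=12), bad)

    def test_needs_at_least_two_windows(self, ramp_windows):
        with pytest.raises(ValueError, match="at least 2"):
            train(build_model(TINY, L=12), _slice_windows(ramp_windows, slice(0, 1)))


@pytest.fixture(scope="module")
def fitted():
    windows = build_windows(_ramp_series(), L=12, PH=6)
    return GlucoseForecaster(windows, TINY).fit(), windows


class TestPredict:

    def test_outputs_are_finite_with_positive_sd(self, fitted):
        results, windows = fitted
        fc = results.predict(windows)
        assert np.all(np.isfinite(fc.mean))
        assert np.all(fc.sd > 0)
        np.testing.assert_array_equal(fc.target_index, windows.target_index)

    def test_permutation_equivariance(self, fitted):
        results, windows = fitted
        perm = np.random.default_rng(0).permutation(windows.n_windows)
        shuffled = _slice_windows(windows, perm)
        fc = results.predict(windows)
        fc_perm = results.predict(shuffled)
        np.testing.assert_allclose(fc_perm.mean, fc.mean[perm], rtol=1e-6)

    def test_scaler_mismatch_rejected(self, fitted):
        results, windows = fitted
        other = build_windows(_ramp_series(slope=-0.5, start=300.0), L=12, PH=6)
        with pytest.raises(ValueError, match="scaler"):
            results.predict(other)

    def test_wrong_history_length_rejected(self, fitted):
        results, _ = fitted
        other = build_windows(_ramp_series(), L=10, PH=6)
        with pytest.raises(ValueError, match="L="):
            results.predict(other)

    def test_functional_wrapper_equals_method(self, fitted):
        results, windows = fitted
        np.testing.assert_array_equal(predict(results, windows).mean, results.predict(windows).mean)


def test_constant_signal_recovery():
    """Trained to convergence on constant glucose, forecasts return that constant."""
    n = 200
    series = PatientSeries(
        patient_id="c", grid_start=datetime(2024, 1, 1), n_index=n, cgm=np.full(n, 120.0),
    )
    windows = build_windows(series, L=12, PH=6)
    cfg = ModelConfig(
        hidden_units=6, dense_sizes=(8, 4), dense_activations=("relu", "relu"),
        batch_size=64, max_epochs=150, patience=150, seed=0,
    )
    results = GlucoseForecaster(windows, cfg).fit()
    fc = results.predict(windows)
    assert np.all(np.abs(fc.mean - 120.0) < 2.0)


def test_summary_mentions_architecture():
    windows = build_windows(_ramp_series(), L=12, PH=6)
    results = GlucoseForecaster(windows, TINY).fit()
    text = results.summary()
    assert "LSTM" in text and "validation NLL" in text and "PH=6" in text
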