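import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmforecast.features import (
    ChannelScaler,
    build_windows,
    effective_carbs,
    effective_insulin,
    step_feature,
)


class TestEffectiveCarbs:
    """Piecewise meal-absorption kinetics: 15-min lag, 45-min rise, ~3-h decay."""

    @pytest.mark.parametrize(
        "index, expected",
        [
            (0, 0.0),  # meal instant: no absorption yet
            (2, 0.0),  # within the ignored first 15 min
            (3, 0.0),  # lag boundary is inclusive
            (6, (6 - 3) * 0.111 * 100),  # rising: 33.3 g
            (12, 9 * 0.111 * 100),  # peak: 99.9 g
            (13, 100 * (1 - 1 * 0.028)),  # first decay step
            (48, 0.0),  # 36 decay steps: 1 - 36*0.028 < 0, clamped
            (60, 0.0),
        ],
    )
    def test_single_meal_profile(self, index, expected):
        c = effective_carbs([(0, 100.0)], 61)
        assert c[index] == pytest.approx(expected, abs=1e-12)

    def test_peak_reaches_nearly_full_meal(self):
        c = effective_carbs([(0, 100.0)], 20)
        assert c.max() == pytest.approx(99.9)
        assert c.max() <= 100.0  # never exceeds the meal amount

    def test_new_meal_replaces_tracked_state(self):
        # second meal at index 10 resets the clock and the amount
        c = effective_carbs([(0, 100.0), (10, 50.0)], 30)
        expected_after = effective_carbs([(0, 50.0)], 20)
        np.testing.assert_allclose(c[10:], expected_after)

    def test_superpose_mode_sums_responses(self):
        both = effective_carbs([(0, 100.0), (10, 50.0)], 40, mode="superpose")
        a = effective_carbs([(0, 100.0)], 40)
        b = effective_carbs([(10, 50.0)], 40)
        np.testing.assert_allclose(both, a + b)

    def test_no_events_means_zero(self):
        assert np.all(effective_carbs([], 50) == 0)

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            effective_carbs([(0, -1.0)], 10)


class TestEffectiveInsulin:
    @pytest.mark.parametrize(
        "index, expected",
        [(0, 5.0), (10, 5.0 - 10 * 0.07), (71, 5.0 - 71 * 0.07), (72, 0.0)],
    )
    def test_single_bolus_decay(self, index, expected):
        i = effective_insulin([(0, 5.0)], 80)
        assert i[index] == pytest.approx(expected, abs=1e-12)

    def test_non_negative_and_zero_without_events(self):
        assert np.all(effective_insulin([], 30) == 0)
        assert np.all(effective_insulin([(5, 1.0)], 300) >= 0)

    def test_negative_units_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            effective_insulin([(0, -0.5)], 10)


class TestStepFeature:
    def test_all_zero(self):
        assert np.all(step_feature(np.zeros(40)) == 0)

    def test_constant_full_history_gain(self):
        # sum of weights (n - i)/n over i=0..9 is 55/10 = 5.5
        s = step_feature(np.full(30, 7.0))
        assert s[15] == pytest.approx(5.5 * 7.0)

    def test_impulse_response(self):
        steps = np.zeros(30)
        steps[5] = 100.0
        s = step_feature(steps)
        expected = [100, 90, 80, 70, 60, 50, 40, 30, 20, 10]
        np.testing.assert_allclose(s[5:15], expected)
        assert np.all(s[15:] == 0) and np.all(s[:5] == 0)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(0, 1e3), min_size=1, max_size=30),
        st.lists(st.floats(0, 1e3), min_size=1, max_size=30),
        st.floats(-2, 2),
        st.floats(-2, 2),
    )
    def test_linearity(self, xs, ys, a, b):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        lhs = step_feature(a * x + b * y)
        rhs = a * step_feature(x) + b * step_feature(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)


class TestBuildWindows:
    def _series(self, cgm, meals=(), boluses=()):
        from datetime import datetime

        from cgmforecast.data_model import PatientSeries

        return PatientSeries(
            patient_id="t",
            grid_start=datetime(2024, 1, 1),
            n_index=len(cgm),
            cgm=np.asarray(cgm, dtype=float),
            meal_events=list(meals),
            bolus_events=list(boluses),
        )

    def test_fully_observed_count(self):
        # t must satisfy t-L+1 >= 0 and t+PH <= 39: t in 23..33 -> 11 windows
        series = self._series(np.linspace(100, 140, 40))
        w = build_windows(series, L=24, PH=6)
        assert w.n_windows == 11
        np.testing.assert_array_equal(w.target_index, np.arange(29, 40))

    def test_gap_in_every_history_gives_zero_windows(self):
        cgm = np.linspace(100, 140, 40)
        cgm[::10] = np.nan  # a hole at least every 10 slots < L=24
        w = build_windows(self._series(cgm), L=24, PH=6)
        assert w.n_windows == 0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.4))
    def test_count_matches_brute_force_under_missingness(self, seed, miss_rate):
        rng = np.random.default_rng(seed)
        n, L, PH = 80, 8, 4
        cgm = rng.uniform(80, 200, n)
        cgm[rng.random(n) < miss_rate] = np.nan
        if not np.isfinite(cgm).any():
            cgm[0] = 100.0
        w = build_windows(self._series(cgm), L=L, PH=PH)
        ok = np.isfinite(cgm)
        expected = sum(
            1
            for t in range(L - 1, n - PH)
            if ok[t - L + 1 : t + 1].all() and ok[t + PH]
        )
        assert w.n_windows == expected

    def test_window_contents_and_target_shift(self):
        series = self._series(np.arange(100, 140, dtype=float), meals=[(0, 60.0)])
        w = build_windows(series, L=24, PH=6)
        np.testing.assert_array_equal(w.inputs[0, :, 0], np.arange(100, 124))
        assert w.targets[0] == 100 + 29  # glucose at index 23 + PH
        assert w.inputs.shape[-1] == 4

    def test_targets_stay_in_physical_units_under_external_scaler(self):
        series = self._series(np.linspace(100, 160, 60))
        train = build_windows(series, L=24, PH=6)
        scaled = train.scaled_inputs()
        assert abs(scaled[..., 0].mean()) < 1e-9  # inputs are standardized
        other = build_windows(series, L=24, PH=6, scaler=train.scaler)
        assert other.scaler is train.scaler
        assert other.targets.min() >= 100  # never scaled
        np.testing.assert_array_equal(other.targets, train.targets)

    @pytest.mark.parametrize("L, PH", [(0, 6), (24, 0)])
    def test_degenerate_lengths_rejected(self, L, PH):
        series = self._series(np.linspace(100, 140, 40))
        with pytest.raises(ValueError):
            build_windows(series, L=L, PH=PH)


def test_scaler_round_trip():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 5, 4)) * 50 + 120
    sc = ChannelScaler.fit(x)
    z = sc.transform(x)
    assert np.allclose(z.reshape(-1, 4).mean(axis=0), 0, atol=1e-9)
    y = rng.uniform(80, 200, 10)
    np.testing.assert_allclose(sc.unscale_mean(sc.scale_target(y)), y)
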