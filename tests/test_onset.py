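"""Teager-Kaiser activity detection and constrained threshold calibration."""

import numpy as np
import pytest

from emgdyn import ThresholdModel, TkeoGate, is_active, tkeo, window_activity
from emgdyn.onset import (
    CalibrationError,
    _activity_batch,
    active_mask,
    calibrate_from_activities,
    default_grid,
)


class TestTkeo:
    def test_hand_computed(self):
        np.testing.assert_allclose(tkeo(np.array([1.0, 2.0, 3.0])), [1.0])

    def test_constant_signal_zero(self):
        np.testing.assert_allclose(tkeo(np.full(50, 3.3)), 0.0, atol=1e-12)

    def test_sinusoid_closed_form(self):
        """psi[A sin(w n)] = A^2 sin^2(w), constant over the signal."""
        A, w = 2.5, 0.3
        n = np.arange(1000)
        y = tkeo(A * np.sin(w * n))
        np.testing.assert_allclose(y, A**2 * np.sin(w) ** 2, atol=1e-6)

    def test_output_length(self):
        assert tkeo(np.arange(10.0)).shape == (8,)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tkeo(np.array([1.0, 2.0]))


class TestWindowActivity:
    def test_zero_window(self):
        np.testing.assert_array_equal(window_activity(np.zeros((3, 64))), 0.0)

    def test_quadratic_amplitude_scaling(self, rng):
        w = rng.standard_normal((2, 128))
        np.testing.assert_allclose(
            window_activity(2.0 * w), 4.0 * window_activity(w), rtol=1e-12
        )

    def test_statistics_agree_on_ordering(self, rng):
        w = rng.standard_normal((1, 128))
        loud = 10 * w
        for stat in ("mean", "max", "sum"):
            assert window_activity(loud, stat)[0] > window_activity(w, stat)[0]

    def test_active_hold_dominates_rest(self, series, protocol):
        acts = _activity_batch(np.asarray(series.data, dtype=float))
        hold = (series.phase_labels == "hold") & (
            series.class_labels != protocol.rest_class
        )
        rest = series.class_labels == protocol.rest_class
        ratio = acts[hold].max(axis=1).mean() / acts[rest].mean(axis=0).max()
        assert ratio > 10.0


class TestIsActive:
    def _model(self, coefficient):
        return ThresholdModel(rest_activity=np.ones(2), coefficient=coefficient)

    def test_single_hot_channel_suffices(self):
        w = np.vstack([np.zeros(64), 5 * np.sin(0.5 * np.arange(64))])
        assert is_active(w, self._model(2.0))

    def test_tiny_coefficient_always_active(self, rng):
        assert is_active(0.01 * rng.standard_normal((2, 64)), self._model(1e-9))

    def test_rest_level_window_inactive(self, series, protocol):
        acts = _activity_batch(np.asarray(series.data, dtype=float))
        rest = series.class_labels == protocol.rest_class
        model = ThresholdModel(
            rest_activity=acts[rest].mean(axis=0), coefficient=3.0
        )
        assert active_mask(acts[rest], model).mean() < 0.01

    def test_coefficient_must_be_positive(self):
        with pytest.raises(ValueError):
            ThresholdModel(rest_activity=np.ones(2), coefficient=0.0)


def _linear_scan_oracle(ratio, labels, grid, overall_min, per_class_min):
    """Independent maximizer: check every grid value, keep the largest
    feasible one."""
    best = None
    for c in grid:
        flag = ratio > c
        ok_all = flag.mean() > overall_min
        ok_cls = all(flag[labels == k].mean() >= per_class_min for k in set(labels))
        if ok_all and ok_cls and (best is None or c > best):
            best = c
    return best


class TestCalibrate:
    def test_uniform_activities_pick_largest_grid_value_below_ratio(self):
        act = np.full((40, 2), 10.0)
        labels = np.repeat([1, 2], 20)
        rest = np.full((30, 2), 1.0)
        model = calibrate_from_activities(act, labels, rest)
        grid = default_grid()
        assert model.coefficient == pytest.approx(grid[grid < 10.0].max())

    def test_infeasible_when_active_below_rest(self):
        act = np.full((40, 2), 0.05)
        labels = np.repeat([1, 2], 20)
        rest = np.full((30, 2), 1.0)
        with pytest.raises(CalibrationError):
            calibrate_from_activities(act, labels, rest)

    def test_vacuous_constraints_take_grid_maximum(self):
        act = np.full((10, 1), 5.0)
        rest = np.full((5, 1), 1.0)
        model = calibrate_from_activities(
            act, np.ones(10), rest, overall_min=-1.0, per_class_min=0.0
        )
        assert model.coefficient == pytest.approx(default_grid().max())

    def test_active_set_shrinks_as_coefficient_grows(self, rng):
        acts = np.abs(rng.standard_normal((200, 3))) + 0.1
        model_lo = ThresholdModel(rest_activity=np.ones(3), coefficient=0.5)
        model_hi = ThresholdModel(rest_activity=np.ones(3), coefficient=2.0)
        lo, hi = active_mask(acts, model_lo), active_mask(acts, model_hi)
        assert np.all(hi <= lo)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_independent_linear_scan(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 120
        labels = rng.integers(1, 4, size=n)
        act = np.abs(rng.lognormal(2.0, 1.0, size=(n, 3)))
        rest = np.abs(rng.lognormal(0.0, 0.3, size=(40, 3)))
        grid = default_grid()
        rest_ref = rest.mean(axis=0)
        ratio = (act / rest_ref).max(axis=1)
        expected = _linear_scan_oracle(ratio, labels, grid, 0.97, 0.85)
        if expected is None:
            with pytest.raises(CalibrationError):
                calibrate_from_activities(act, labels, rest)
        else:
            model = calibrate_from_activities(act, labels, rest)
            assert model.coefficient == pytest.approx(expected)

    def test_json_round_trip(self, tmp_path):
        model = ThresholdModel(rest_activity=np.array([1.0, 2.0]), coefficient=3.5)
        path = tmp_path / "gate.json"
        model.to_json(path)
        back = ThresholdModel.from_json(path)
        np.testing.assert_array_equal(back.rest_activity, model.rest_activity)
        assert back.coefficient == model.coefficient


class TestTkeoGate:
    def test_fit_predict_on_synthetic_windows(self, series, protocol):
        labels = series.class_labels.copy()
        hold = series.phase_labels == "hold"
        rest = labels == protocol.rest_class
        keep = rest | hold
        X = np.asarray(series.data, dtype=float)[keep]
        y = labels[keep]
        gate = TkeoGate(rest_label=protocol.rest_class).fit(X, y)
        assert gate.coefficient_ > 1.0
        pred = gate.predict(X)
        # hold windows of active classes overwhelmingly active
        assert pred[y != protocol.rest_class].mean() > 0.9
        assert pred[y == protocol.rest_class].mean() < 0.05
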