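"""Interestingness-function tests: logistic squash and online spline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamtriage.interest import (
    EmptySplineError,
    LogisticParams,
    SplineModel,
    calibrate_logistic,
    logistic_if,
    make_if,
    spline_estimate,
    spline_update,
)

finite = st.floats(-50, 50, allow_nan=False)


class TestLogistic:
    def test_midpoint_maps_to_half(self):
        assert logistic_if(-1.4, LogisticParams(4.5, -1.4)) == pytest.approx(0.5, abs=1e-12)

    def test_known_value(self):
        # 1/(1+exp(-4.5*0.4)) evaluated independently
        assert logistic_if(-1.0, LogisticParams(4.5, -1.4)) == pytest.approx(0.858149, abs=1e-6)

    def test_saturation(self):
        p = LogisticParams(4.5, -1.4)
        assert logistic_if(-1.4 + 30 / 4.5, p) >= 1 - 1e-12
        assert logistic_if(1e6, p) < 1.0  # open interval even in saturation
        assert logistic_if(-1e6, p) > 0.0

    @settings(deadline=None, derandomize=True)
    @given(x=finite, k=finite, x0=finite)
    def test_matches_closed_form(self, x, k, x0):
        z = k * (x - x0)
        expected = 0.0 if z < -700 else 1.0 / (1.0 + math.exp(-z))
        got = logistic_if(x, LogisticParams(k, x0))
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0.0 < got < 1.0

    def test_monotone_in_x_for_positive_k(self):
        p = LogisticParams(2.0, 0.3)
        xs = np.sort(np.random.default_rng(0).uniform(-10, 10, 500))
        ys = [logistic_if(x, p) for x in xs]
        assert np.all(np.diff(ys) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            logistic_if(float("nan"))

    def test_calibration_places_references_symmetrically(self):
        params = calibrate_logistic([-5.0, -4.0], [-1.0, 0.0], spread=3.0)
        assert logistic_if(-4.5, params) == pytest.approx(1 / (1 + math.exp(3)), abs=1e-12)
        assert logistic_if(-0.5, params) == pytest.approx(1 / (1 + math.exp(-3)), abs=1e-12)
        assert logistic_if(-2.5, params) == pytest.approx(0.5, abs=1e-12)


class TestSpline:
    def test_linear_midpoint(self):
        m = SplineModel((0.0, 10.0), (0.5, 0.1))
        assert spline_estimate(m, 5.0) == pytest.approx(0.3, abs=1e-12)

    def test_exact_at_knots(self):
        rng = np.random.default_rng(7)
        idx = np.sort(rng.choice(200, size=10, replace=False)).astype(float)
        rho = rng.uniform(0, 2, 10)
        m = SplineModel(tuple(idx), tuple(rho))
        for i, r in zip(idx, rho):
            assert spline_estimate(m, i) == r

    def test_clamped_extrapolation(self):
        m = SplineModel((0.0, 10.0), (0.5, 0.1))
        assert spline_estimate(m, 12.0) == 0.1
        assert spline_estimate(m, -3.0) == 0.5

    def test_single_knot_clamps_everywhere(self):
        m = spline_update(SplineModel(), 3.0, 0.2)
        for q in (-10, 0, 3, 100):
            assert spline_estimate(m, q) == 0.2

    def test_update_replaces_existing_knot(self):
        m = SplineModel((0.0, 5.0), (1.0, 2.0))
        m2 = spline_update(m, 5.0, 9.0)
        assert spline_estimate(m2, 5.0) == 9.0
        assert spline_estimate(m2, 0.0) == 1.0  # other knots untouched
        assert spline_estimate(m, 5.0) == 2.0  # original immutable

    def test_reconstructs_linear_function_from_its_samples(self):
        m = SplineModel()
        for i in (0.0, 10.0, 5.0):
            m = spline_update(m, i, 0.5 - 0.04 * i)
        assert spline_estimate(m, 7.0) == pytest.approx(0.22, abs=1e-12)

    def test_empty_model_raises(self):
        with pytest.raises(EmptySplineError):
            spline_estimate(SplineModel(), 0.0)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            spline_update(SplineModel(), 0.0, -0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 5)), min_size=1, max_size=20),
           st.floats(-10, 110))
    def test_estimate_bounded_by_knot_values(self, knots, query):
        m = SplineModel()
        for i, r in knots:
            m = spline_update(m, i, r)
        est = spline_estimate(m, query)
        assert min(m.rhos) - 1e-12 <= est <= max(m.rhos) + 1e-12

    def test_refinement_reduces_rmse_on_smooth_target(self):
        """More knots sampled from a smooth oscillating target -> lower RMSE."""
        t_all = np.arange(128)
        target = 0.3 + 0.2 * np.sin(2 * np.pi * t_all / 32)

        def rmse(n_knots, seed):
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(128, size=n_knots, replace=False))
            m = SplineModel()
            for i in idx:
                m = spline_update(m, float(i), float(target[i]))
            est = np.array([spline_estimate(m, float(t)) for t in t_all])
            return np.sqrt(np.mean((est - target) ** 2))

        means = [np.mean([rmse(k, s) for s in range(20)]) for k in (4, 8, 16)]
        assert means[0] >= means[1] >= means[2]


class TestRegistry:
    def test_logistic_binding_uses_plls(self):
        from streamtriage.features import FeatureVector

        fn = make_if("logistic", {"k": 4.5, "x0": -1.4})
        assert fn(FeatureVector(-1.4, 0.0, 1.0)) == pytest.approx(0.5, abs=1e-12)

    def test_spline_binding(self):
        fn = make_if("spline", {"indices": [0, 10], "rhos": [0.5, 0.1]})
        assert fn(5.0) == pytest.approx(0.3, abs=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            make_if("neural")
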