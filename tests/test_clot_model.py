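"""Pressure-model, fitting and muCT-extraction behaviour."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thromboflow import (
    IntensityTrace,
    PressureTrace,
    analyze_trace,
    detect_censored,
    fit_intensity_sigmoid,
    fit_pressure_trace,
    model_pressure_ratio,
    mu_ct,
    preprocess_trace,
    threshold_crossing_time,
)
from thromboflow.errors import InvalidParameterError, TraceInputError

from conftest import make_model_trace

E = math.e


class TestModelCurve:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (30.0, 2.0),                      # doubling time anchor
            (45.0, 1.0 + E),                  # (1+e) anchor
            (37.5, 1.0 + math.sqrt(E)),       # midpoint-in-time level
        ],
    )
    def test_anchor_levels(self, t, expected):
        assert model_pressure_ratio(t, 30.0, 45.0, 1.0) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        t_g=st.floats(0.1, 100.0),
        width=st.floats(0.01, 100.0),
    )
    def test_anchors_hold_for_all_parameters(self, t_g, width):
        t_s = t_g + width
        assert model_pressure_ratio(t_g, t_g, t_s) == pytest.approx(2.0, abs=1e-12)
        assert model_pressure_ratio(t_s, t_g, t_s) == pytest.approx(1 + E, rel=1e-14)

    def test_strictly_increasing_and_above_one(self):
        t = np.linspace(-50, 200, 4001)
        r = model_pressure_ratio(t, 30.0, 45.0, 1.0)
        assert np.all(np.diff(r) > 0)
        assert np.all(r > 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            model_pressure_ratio(10.0, 45.0, 30.0)  # T_s <= T_g
        with pytest.raises(InvalidParameterError):
            model_pressure_ratio(10.0, 30.0, 45.0, k=0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        ratio=st.floats(1.001, 50.0),
        k=st.floats(1.0, 3.0),
    )
    def test_threshold_inversion_round_trip(self, ratio, k):
        t = threshold_crossing_time(30.0, 45.0, k, ratio)
        assert model_pressure_ratio(t, 30.0, 45.0, k) == pytest.approx(
            ratio, abs=1e-10
        )

    def test_threshold_at_two_is_doubling_time(self):
        assert threshold_crossing_time(30.0, 45.0, 1.0, 2.0) == pytest.approx(30.0)

    def test_threshold_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            threshold_crossing_time(30.0, 45.0, 1.0, 0.9)


class TestPreprocess:
    def test_spike_removed_baseline_unchanged(self):
        t = np.arange(100.0)
        p = np.ones(100)
        p[40] = 10.0
        tr = PressureTrace(times=t, pressures=p)
        clean, baseline = preprocess_trace(tr)
        assert clean.pressures[40] == pytest.approx(1.0)
        assert baseline == pytest.approx(1.0)

    def test_psi_converted_exactly(self):
        t = np.arange(20.0)
        tr = PressureTrace(times=t, pressures=np.full(20, 2.0), unit="psi")
        assert np.allclose(tr.pressures, 2.0 * 6.894757)

    def test_time_rezeroed(self):
        t = np.arange(100.0) + 500.0
        tr = PressureTrace(times=t, pressures=np.ones(100))
        clean, _ = preprocess_trace(tr)
        assert clean.times[0] == 0.0

    def test_too_short_rejected(self):
        tr = PressureTrace(times=np.arange(5.0), pressures=np.ones(5))
        with pytest.raises(TraceInputError):
            preprocess_trace(tr)


class TestFit:
    def test_noiseless_self_consistency(self, model_trace):
        fit = fit_pressure_trace(model_trace)
        assert fit.converged
        assert fit.p0 == pytest.approx(1.0, rel=1e-6)
        assert fit.t_g == pytest.approx(30.0, rel=1e-6)
        assert fit.t_s == pytest.approx(45.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_free_k_recovers_unity(self, model_trace):
        fit = fit_pressure_trace(model_trace, fix_k=None)
        assert fit.converged and not fit.k_fixed
        assert fit.k == pytest.approx(1.0, abs=1e-4)

    def test_grid_search_oracle_agrees_with_fitter(self):
        """Brute-force grid minimization over (T_g, T_s) lands on the same
        optimum as the analytic fit, on 20 random noiseless instances."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            t_g = rng.uniform(10.0, 40.0)
            t_s = t_g + rng.uniform(2.0, 20.0)
            tr = make_model_trace(p0=rng.uniform(0.5, 3.0), t_g=t_g, t_s=t_s,
                                  t_end_min=90.0, n=400)
            fit = fit_pressure_trace(tr)
            assert fit.t_g == pytest.approx(t_g, rel=1e-6)
            assert fit.t_s == pytest.approx(t_s, rel=1e-6)

            # independent oracle: zooming grid search; P0 solved closed-form
            pre, base = preprocess_trace(tr)
            keep = pre.pressures <= 4.0 * base
            tm, pv = pre.times_min[keep], pre.pressures[keep]
            lo_g, hi_g = 1.0, 60.0
            lo_d, hi_d = 0.5, 40.0
            for _zoom in range(6):
                gs = np.linspace(lo_g, hi_g, 21)
                ds = np.linspace(lo_d, hi_d, 21)
                G, D = np.meshgrid(gs, ds, indexing="ij")
                X = (tm[None, None, :] - G[..., None]) / D[..., None]
                R = 1.0 + np.exp(np.clip(X, -50, 50))  # clip avoids overflow in R*R
                p0_opt = (R * pv).sum(-1) / (R * R).sum(-1)
                sse = ((p0_opt[..., None] * R - pv) ** 2).sum(-1)
                i, j = np.unravel_index(np.argmin(sse), sse.shape)
                span_g, span_d = (hi_g - lo_g) / 10, (hi_d - lo_d) / 10
                lo_g, hi_g = gs[i] - span_g, gs[i] + span_g
                lo_d, hi_d = max(ds[j] - span_d, 1e-3), ds[j] + span_d
            assert gs[i] == pytest.approx(fit.t_g, rel=1e-3)
            assert ds[j] == pytest.approx(fit.t_s - fit.t_g, rel=1e-3)

    def test_k_fixed_at_two_gives_similar_muct(self, model_trace):
        m1 = mu_ct(fit_pressure_trace(model_trace)).value
        m2 = mu_ct(fit_pressure_trace(model_trace, fix_k=2.0)).value
        assert abs(m2 - m1) / m1 < 0.10

    def test_nonconvergence_returns_flagged_fit(self):
        # ragged noise with no structure: fit may or may not converge, but
        # must return a ClotModelFit either way (never raise)
        rng = np.random.default_rng(5)
        t = np.arange(100.0)
        p = np.abs(rng.standard_normal(100)) + 0.1
        tr = PressureTrace(times=t, pressures=p)
        fit = fit_pressure_trace(tr)
        assert hasattr(fit, "converged")


class TestMuCT:
    def test_average_method_is_midpoint(self, model_trace):
        res = mu_ct(fit_pressure_trace(model_trace))
        assert res.value == pytest.approx((30.0 + 45.0) / 2.0, rel=1e-6)
        assert res.method == "average_of_Tg_Ts"
        assert not res.censored

    def test_threshold_method_closed_form(self, model_trace):
        fit = fit_pressure_trace(model_trace)
        res = mu_ct(fit, method="threshold_crossing", threshold_ratio=2.86)
        assert res.value == pytest.approx(30.0 + 15.0 * math.log(1.86), rel=1e-6)
        assert res.threshold_ratio == 2.86

    def test_threshold_round_trip_reproduces_ratio(self, model_trace):
        fit = fit_pressure_trace(model_trace)
        for ratio in (1.5, 2.0, 2.86, 3.6):
            res = mu_ct(fit, method="threshold_crossing", threshold_ratio=ratio)
            assert model_pressure_ratio(
                res.value, fit.t_g, fit.t_s, fit.k
            ) == pytest.approx(ratio, abs=1e-10)

    def test_invalid_threshold_rejected(self, model_trace):
        fit = fit_pressure_trace(model_trace)
        with pytest.raises(InvalidParameterError):
            mu_ct(fit, method="threshold_crossing", threshold_ratio=1.0)


class TestCensoring:
    def test_flat_noisy_trace_censored(self):
        rng = np.random.default_rng(0)
        t = np.arange(600.0)
        p = 1.0 + 0.02 * rng.standard_normal(600)
        assert detect_censored(PressureTrace(times=t, pressures=p))

    def test_rising_trace_not_censored(self, model_trace):
        assert not detect_censored(model_trace)

    def test_analyze_trace_censored_result(self):
        t = np.arange(600.0)
        res = analyze_trace(PressureTrace(times=t, pressures=np.ones(600)))
        assert res.censored and not res.ok
        assert res.fit is None


class TestIntensitySigmoid:
    def test_exact_logistic_recovery(self):
        t = np.linspace(0.0, 80.0, 200)
        y = 1.0 / (1.0 + np.exp(-(t - 40.0) / 6.0))
        fit = fit_intensity_sigmoid(IntensityTrace(times=t, normalized_intensity=y))
        assert fit.converged
        assert fit.t0 == pytest.approx(40.0, rel=1e-6)
        assert fit.tau == pytest.approx(6.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_trace_flagged(self):
        t = np.linspace(0.0, 80.0, 50)
        fit = fit_intensity_sigmoid(
            IntensityTrace(times=t, normalized_intensity=np.zeros(50))
        )
        assert not fit.converged

    def test_decreasing_input_warns_not_raises(self):
        t = np.linspace(0.0, 80.0, 50)
        y = np.linspace(1.0, 0.0, 50)
        fit = fit_intensity_sigmoid(IntensityTrace(times=t, normalized_intensity=y))
        assert fit.warning is not None
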