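"""Occlusion simulator: calibration, ground truth, noise, censoring."""
import dataclasses
import math

import numpy as np
import pytest

from thromboflow import (
    CENSORED,
    DoseResponseParams,
    SampleCondition,
    SimulationConfig,
    analyze_trace,
    fit_intensity_sigmoid,
    sample_channel_params,
    simulate_cohort,
    simulate_constant_flow,
    simulate_constant_pressure,
    simulate_intensity,
    target_mu_ct,
)
from thromboflow.errors import ConfigError
from thromboflow.presets import cohort_design
from thromboflow.simulate import network_resistance_at, open_fractions, per_channel_flows


class TestTargetMuCT:
    def test_monotone_increasing_in_heparin(self):
        g = 1225.0
        vals = [
            target_mu_ct(SampleCondition(heparin=h, shear_gradient=g))
            for h in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]

    def test_monotone_decreasing_in_gradient(self):
        vals = [
            target_mu_ct(SampleCondition(heparin=0.5, shear_gradient=g))
            for g in (262.0, 1225.0, 4375.0, 8750.0)
        ]
        assert vals == sorted(vals, reverse=True)

    def test_exactly_linear_in_heparin_at_fixed_gradient(self):
        g = 1225.0
        h = np.array([0.0, 0.3, 0.6, 0.9])
        v = np.array([target_mu_ct(SampleCondition(heparin=x, shear_gradient=g))
                      for x in h])
        slopes = np.diff(v) / np.diff(h)
        assert np.allclose(slopes, slopes[0])

    def test_collagen_shortens(self):
        bare = target_mu_ct(SampleCondition(shear_gradient=4375.0))
        coated = target_mu_ct(SampleCondition(shear_gradient=4375.0, coating="collagen"))
        assert coated < bare

    def test_abciximab_dose_dependent_rise(self):
        vals = [
            target_mu_ct(SampleCondition(
                shear_gradient=4375.0, coating="collagen",
                drug="abciximab", drug_dose=d,
            ))
            for d in (0.0, 5.0, 20.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_aspirin_plavix_prolongs(self):
        base = SampleCondition(shear_gradient=4375.0, coating="collagen")
        treated = dataclasses.replace(base, drug="aspirin_plavix")
        assert target_mu_ct(treated) > target_mu_ct(base)

    def test_hps_censored_without_adp(self):
        for g, adp in ((4375.0, 0.0), (8750.0, 0.0), (4375.0, 5.0)):
            c = SampleCondition(disease="hps", shear_gradient=g, adp=adp)
            assert target_mu_ct(c) == CENSORED

    def test_hps_adp_rescue_decreasing_in_dose(self):
        lo = target_mu_ct(SampleCondition(disease="hps", adp=7.5))
        hi = target_mu_ct(SampleCondition(disease="hps", adp=10.0))
        assert math.isfinite(lo) and math.isfinite(hi)
        assert hi < lo


class TestChannelCalibration:
    def test_zero_jitter_gives_identical_channels(self, default_condition):
        cfg = SimulationConfig(seed=3, channel_jitter_cv=0.0)
        channels = sample_channel_params(
            default_condition, cfg, np.random.default_rng(3)
        )
        onsets = {c.onset_time for c in channels}
        assert len(onsets) == 1

    def test_censored_condition_gets_infinite_onsets(self):
        cfg = SimulationConfig(seed=3)
        cond = SampleCondition(disease="hps", adp=0.0, shear_gradient=4375.0)
        channels = sample_channel_params(cond, cfg, np.random.default_rng(3))
        assert all(math.isinf(c.onset_time) for c in channels)

    def test_two_seeds_same_calibrated_muct(self, default_condition):
        """Different onset draws, but the noiseless device-level muCT is
        calibrated to the same target within 2%."""
        target = target_mu_ct(default_condition)
        for seed in (11, 22):
            cfg = SimulationConfig(seed=seed, noise_cv=0.0)
            _, truth = simulate_constant_flow(cfg, default_condition)
            assert truth.mu_ct_true == pytest.approx(target, rel=0.02)


class TestConstantFlow:
    def test_initial_pressure_is_open_network_drop(self, config, default_condition):
        trace, truth = simulate_constant_flow(config, default_condition)
        t0_resistance = network_resistance_at(truth.channels, np.array([0.0]), config)
        q_m3 = trace.flow_rate * 1e-9 / 60.0
        expected_kpa = q_m3 * t0_resistance[0] / 1000.0
        # noise cv 2%: the first sample sits near the open-network drop
        assert trace.pressures[0] == pytest.approx(expected_kpa, rel=0.1)

    def test_noiseless_trace_nondecreasing(self, default_condition):
        cfg = SimulationConfig(seed=8, noise_cv=0.0)
        trace, _ = simulate_constant_flow(cfg, default_condition)
        assert np.all(np.diff(trace.pressures) >= -1e-12)

    def test_noiseless_fit_matches_ground_truth(self, default_condition):
        cfg = SimulationConfig(seed=8, noise_cv=0.0)
        trace, truth = simulate_constant_flow(cfg, default_condition)
        res = analyze_trace(trace)
        assert res.value == pytest.approx(truth.mu_ct_true, rel=0.02)

    def test_determinism_bit_identical(self, default_condition):
        a, ta = simulate_constant_flow(SimulationConfig(seed=77), default_condition)
        b, tb = simulate_constant_flow(SimulationConfig(seed=77), default_condition)
        assert np.array_equal(a.pressures, b.pressures)
        assert np.array_equal(a.times, b.times)
        assert ta.mu_ct_true == tb.mu_ct_true

    def test_flow_conservation_across_channels(self, config, default_condition):
        _, truth = simulate_constant_flow(config, default_condition)
        t = np.linspace(0.0, 40.0, 50)
        q = per_channel_flows(truth.channels, t, config, total_flow=47.0)
        assert np.allclose(q.sum(axis=1), 47.0, rtol=1e-9)
        # parallel identity: Q_i R_i equal across channels at each instant
        from thromboflow.haemodynamics import rectangular_duct_resistance
        geo = config.geometry
        r_open = rectangular_duct_resistance(
            geo.channel_width, geo.channel_height, geo.channel_length
        )
        r = r_open * open_fractions(truth.channels, t) ** (-config.k_sim)
        drops = q * r
        assert np.allclose(drops, drops[:, :1], rtol=1e-9)

    def test_hps_high_gradient_run_is_censored(self):
        cond = SampleCondition(disease="hps", adp=0.0, shear_gradient=8750.0,
                              coating="collagen")
        cfg = SimulationConfig(seed=21, duration=20.0)
        trace, truth = simulate_constant_flow(cfg, cond)
        assert truth.censored and truth.mu_ct_true == CENSORED
        assert analyze_trace(trace).censored

    def test_occlusion_floor_barely_moves_muct(self, default_condition):
        vals = []
        for floor in (0.02, 0.01):
            cfg = SimulationConfig(seed=5, noise_cv=0.0, floor_fraction=floor)
            _, truth = simulate_constant_flow(cfg, default_condition)
            vals.append(truth.mu_ct_true)
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01

    def test_muct_recovery_within_five_percent(self):
        """Median relative muCT error vs ground truth < 5% at default noise
        over a heparin x gradient grid (>= 30 runs)."""
        errs = []
        for h in (0.0, 0.5, 1.0):
            for g in (525.0, 1225.0, 5250.0):
                for seed in (1, 2, 3, 4):
                    cond = SampleCondition(heparin=h, shear_gradient=g)
                    trace, truth = simulate_constant_flow(
                        SimulationConfig(seed=seed), cond
                    )
                    res = analyze_trace(trace)
                    errs.append(abs(res.value - truth.mu_ct_true) / truth.mu_ct_true)
        assert np.median(errs) < 0.05


class TestConstantPressure:
    def test_flow_times_resistance_equals_driving_pressure(self, default_condition):
        cfg = SimulationConfig(seed=9, mode="constant_pressure", noise_cv=0.0,
                              driving_pressure=5.0)
        trace, truth = simulate_constant_pressure(cfg, default_condition)
        r = network_resistance_at(truth.channels, trace.times_min, cfg)
        q_m3 = trace.flows * 1e-9 / 60.0
        assert np.allclose(q_m3 * r / 1000.0, 5.0, rtol=1e-9)

    def test_noiseless_flow_nonincreasing(self, default_condition):
        cfg = SimulationConfig(seed=9, mode="constant_pressure", noise_cv=0.0)
        trace, _ = simulate_constant_pressure(cfg, default_condition)
        assert np.all(np.diff(trace.flows) <= 1e-12)

    def test_open_network_initial_flow(self, default_condition):
        cfg = SimulationConfig(seed=9, mode="constant_pressure", noise_cv=0.0,
                              driving_pressure=5.0)
        trace, truth = simulate_constant_pressure(cfg, default_condition)
        r0 = network_resistance_at(truth.channels, np.array([0.0]), cfg)[0]
        assert trace.flows[0] == pytest.approx(5000.0 / r0 / (1e-9 / 60.0), rel=1e-9)

    def test_wrong_mode_rejected(self, default_condition):
        with pytest.raises(ConfigError):
            simulate_constant_pressure(SimulationConfig(seed=1), default_condition)


class TestIntensity:
    def test_midpoint_value_and_saturation(self, default_condition):
        cfg = SimulationConfig(seed=4, noise_cv=0.0)
        channels = sample_channel_params(
            default_condition, cfg, np.random.default_rng(4)
        )
        mid = float(np.mean([c.onset_time for c in channels]))
        trace = simulate_intensity(default_condition, cfg)
        i_mid = np.interp(mid, trace.times, trace.normalized_intensity)
        assert i_mid == pytest.approx(0.5, abs=0.1)
        assert trace.normalized_intensity[-1] > 0.9

    def test_logistic_fit_quality_at_default_noise(self, default_condition):
        trace = simulate_intensity(default_condition, SimulationConfig(seed=4))
        fit = fit_intensity_sigmoid(trace)
        assert fit.converged and fit.r_squared >= 0.95

    def test_censored_condition_flat(self):
        cond = SampleCondition(disease="hps", adp=0.0, shear_gradient=4375.0)
        trace = simulate_intensity(cond, SimulationConfig(seed=4, duration=20.0))
        assert trace.normalized_intensity.max() < 0.2


class TestCohort:
    def test_design_sizes_and_columns(self, tmp_path):
        design = cohort_design("heparin-validation")  # 4 doses x 3 reps
        cfg = SimulationConfig(seed=42)
        manifest, traces = simulate_cohort(design, cfg, out_dir=tmp_path)
        assert len(manifest) == 12 and len(traces) == 12
        assert manifest["run_id"].is_unique
        assert set(manifest["heparin"]) == {0.0, 0.1, 0.5, 1.0}
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "config.yaml").exists()
        assert all((tmp_path / f).exists() for f in manifest["file"])

    def test_empty_design_gives_empty_manifest(self):
        manifest, traces = simulate_cohort([], SimulationConfig(seed=1))
        assert len(manifest) == 0 and traces == []

    def test_cohort_rerun_bit_identical(self):
        design = cohort_design("shear-validation", replicates=1)
        m1, t1 = simulate_cohort(design, SimulationConfig(seed=5))
        m2, t2 = simulate_cohort(design, SimulationConfig(seed=5))
        assert m1.equals(m2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.pressures, b.pressures)

    def test_ground_truth_monotone_across_presets(self):
        hep, _ = simulate_cohort(
            cohort_design("heparin-titration", replicates=1),
            SimulationConfig(seed=6),
        )
        means = hep.groupby("heparin")["mu_ct_true_min"].mean()
        assert means.is_monotonic_increasing
        shear, _ = simulate_cohort(
            cohort_design("shear-sweep", replicates=1), SimulationConfig(seed=6)
        )
        means = shear.groupby("shear_gradient")["mu_ct_true_min"].mean()
        assert means.is_monotonic_decreasing


def test_missing_seed_rejected():
    with pytest.raises((ConfigError, TypeError)):
        SimulationConfig(seed=None)


def test_nonpositive_target_rejected():
    params = DoseResponseParams(beta0=-50.0, mu_floor=0.0)
    with pytest.raises(ConfigError):
        target_mu_ct(SampleCondition(heparin=0.0, shear_gradient=262.0), params)
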