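"""Synthetic-data generator: sigmoidal occlusion of the channel network.

Each of the device's parallel channels occludes independently: its open
cross-sectional area decays as a falling logistic from 1 to a small floor,
with a per-channel onset time drawn log-normally around a condition-
dependent location ("every section will not occlude equally at the same
time").  Channel resistances rise as open_fraction^(-k_sim); the network
(parallel channels plus series tubing/reservoir elements) then yields

* constant-flow mode:      dP(t) = Q * R_total(t)   (rising, reciprocal-sigmoid)
* constant-pressure mode:  Q(t)  = dP / R_total(t)  (sigmoidal decay)

Multiplicative log-normal sensor noise is applied on top.  The
condition -> clotting-time map is phenomenological:

    muCT*(condition) = (beta0 + beta1 * heparin) * exp(-G / G0) + mu_floor

scaled by coating and drug factors, with Hermansky-Pudlak (HPS) samples
censored unless rescued by ADP.  Per-run ground truth is *operational*: the
same model fit + muCT extraction applied to the noiseless trace, so
recovery tests isolate noise/fitting error.  Per-channel onsets are
calibrated so that the noiseless device-level muCT equals the target;
because onsets and growth widths scale together, the noiseless trace is an
exact time-rescaling of a unit-location trace and the calibration is a
single fit plus one rescale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import haemodynamics as hd
from .clot_model import analyze_trace, fit_pressure_trace, mu_ct
from .conditions import SampleCondition
from .errors import ConfigError, InvalidParameterError
from .traces import FlowTrace, IntensityTrace, PressureTrace

__all__ = [
    "CENSORED",
    "DoseResponseParams",
    "ChannelOcclusionState",
    "SimulationConfig",
    "GroundTruth",
    "target_mu_ct",
    "sample_channel_params",
    "open_fractions",
    "network_resistance_at",
    "per_channel_flows",
    "simulate_constant_flow",
    "simulate_constant_pressure",
    "simulate_intensity",
    "simulate_cohort",
]

#: sentinel for a run that never clots
CENSORED = math.inf


@dataclass(frozen=True)
class DoseResponseParams:
    """Defaults of the condition -> clotting-time map (all configurable).

    Chosen to place simulated muCT values in the device's working range of
    roughly 4-40 min: heparin raises clotting time linearly (slope ``beta1``
    min per IU/ml), the shear gradient G shortens it exponentially with
    scale ``g0``, and ``mu_floor`` is the shear-independent floor.  Collagen
    coating multiplies muCT by ``collagen_factor`` (< 1, faster clotting);
    abciximab scales it by (1 + ``abciximab_slope`` * dose); chronic
    aspirin+clopidogrel by ``aspirin_plavix_factor``.  HPS samples do not
    clot below ``hps_adp_threshold`` uM ADP; above it the rescued clotting
    time falls linearly with ADP dose down to ``hps_rescue_min``.
    """

    beta0: float = 12.0  # min, zero-heparin amplitude
    beta1: float = 25.0  # min per IU ml^-1
    g0: float = 3000.0  # s^-1 mm^-1, exponential decay scale
    mu_floor: float = 4.0  # min
    collagen_factor: float = 0.45
    abciximab_slope: float = 0.05  # per ug ml^-1
    aspirin_plavix_factor: float = 1.6
    hps_adp_threshold: float = 7.5  # uM
    hps_rescue_base: float = 8.5  # min at threshold ADP
    hps_rescue_slope: float = 1.2  # min per uM above threshold
    hps_rescue_min: float = 2.0  # min


@dataclass(frozen=True)
class ChannelOcclusionState:
    """Occlusion kinetics of one channel.

    Open-area fraction a(t) = floor + (1 - floor) / (1 + exp((t - onset)/width)):
    a falling logistic with midpoint ``onset_time`` (min) and width
    ``growth_width`` (min).  Infinite onset means the channel never occludes.
    """

    onset_time: float  # min; inf = never clots
    growth_width: float  # min
    floor_fraction: float = 0.02
    k_sim: float = 2.0

    def __post_init__(self) -> None:
        if not (self.onset_time > 0):
            raise InvalidParameterError("onset_time must be positive (or inf)")
        if math.isfinite(self.onset_time) and not (self.growth_width > 0):
            raise InvalidParameterError("growth_width must be positive")
        if not (0 < self.floor_fraction < 0.5):
            raise InvalidParameterError("floor_fraction must be in (0, 0.5)")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the simulator needs besides the sample condition.

    ``seed`` is mandatory and recorded in all outputs.  ``flow_rate`` (ul/min,
    constant-flow mode) defaults to the flow that realizes the condition's
    shear gradient through the haemodynamics mapping; ``driving_pressure``
    (kPa) is used in constant-pressure mode.
    """

    seed: int
    geometry: hd.DeviceGeometry = hd.DeviceGeometry()
    viscosity: hd.ViscosityModel = hd.ViscosityModel()
    mode: str = "constant_flow"  # constant_flow | constant_pressure
    flow_rate: Optional[float] = None  # ul min^-1
    driving_pressure: Optional[float] = None  # kPa
    sample_dt: float = 1.0  # s
    duration: float = 60.0  # min
    noise_cv: float = 0.02  # multiplicative sensor noise
    channel_jitter_cv: float = 0.15  # spread of onset times across channels
    growth_width_ratio: float = 0.2  # growth width as fraction of onset
    floor_fraction: float = 0.02
    k_sim: float = 2.0
    series_fraction: float = 0.05  # series elements vs open-network resistance
    sensor_ceiling_psi: float = 12.0
    dose_response: DoseResponseParams = DoseResponseParams()

    def __post_init__(self) -> None:
        if self.mode not in ("constant_flow", "constant_pressure"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.sample_dt <= 0 or self.duration <= 0:
            raise ConfigError("sample_dt and duration must be positive")
        if self.noise_cv < 0 or self.channel_jitter_cv < 0:
            raise ConfigError("noise/jitter cv must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is mandatory and must be an integer")


@dataclass(frozen=True)
class GroundTruth:
    """Per-run truth for recovery tests.

    ``mu_ct_true`` is *operational*: the model fit + muCT extraction applied
    to the noiseless trace (inf when censored), not the generating target —
    so estimator error measured against it reflects noise and fitting only.
    """

    mu_ct_true: float  # min; inf = censored
    censored: bool
    target: float  # the condition's target muCT (min; inf = censored)
    channels: tuple[ChannelOcclusionState, ...]
    seed: int
    dose_response: DoseResponseParams = DoseResponseParams()


def target_mu_ct(
    condition: SampleCondition, params: DoseResponseParams = DoseResponseParams()
) -> float:
    """Condition's target clotting time (min), or ``CENSORED`` (inf).

    Linear in heparin at fixed gradient, exponential decay in the gradient at
    fixed heparin, scaled by coating/drug factors; HPS is censored below the
    ADP rescue threshold and rescued (linearly decreasing in ADP) above it.
    """
    if condition.disease == "hps":
        if condition.adp < params.hps_adp_threshold:
            return CENSORED
        value = params.hps_rescue_base - params.hps_rescue_slope * (
            condition.adp - params.hps_adp_threshold
        )
        return max(value, params.hps_rescue_min)

    value = (
        params.beta0 + params.beta1 * condition.heparin
    ) * math.exp(-condition.shear_gradient / params.g0) + params.mu_floor
    if condition.coating == "collagen":
        value *= params.collagen_factor
    if condition.drug == "abciximab":
        value *= 1.0 + params.abciximab_slope * condition.drug_dose
    elif condition.drug == "aspirin_plavix":
        value *= params.aspirin_plavix_factor
    if value <= 0:
        raise ConfigError("dose-response parameters give non-positive muCT")
    return value


def open_fractions(
    channels: Sequence[ChannelOcclusionState], t_min: np.ndarray
) -> np.ndarray:
    """Open-area fraction per channel, shape (len(t_min), n_channels)."""
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    out = np.ones((t.size, len(channels)))
    for j, ch in enumerate(channels):
        if not math.isfinite(ch.onset_time):
            continue
        x = np.clip((t - ch.onset_time) / ch.growth_width, -500, 500)
        out[:, j] = ch.floor_fraction + (1.0 - ch.floor_fraction) / (1.0 + np.exp(x))
    return out


def _r_open(config: SimulationConfig) -> float:
    return hd.rectangular_duct_resistance(
        config.geometry.channel_width,
        config.geometry.channel_height,
        config.geometry.channel_length,
        config.viscosity,
    )


def network_resistance_at(
    channels: Sequence[ChannelOcclusionState],
    t_min: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Total network resistance (Pa·s·m^-3) at each time (minutes)."""
    r_open = _r_open(config)
    frac = open_fractions(channels, t_min)
    r_ch = r_open * frac ** (-config.k_sim)
    n = config.geometry.n_channels
    r_series = config.series_fraction * (r_open / n)
    return 1.0 / np.sum(1.0 / r_ch, axis=1) + r_series


def per_channel_flows(
    channels: Sequence[ChannelOcclusionState],
    t_min: np.ndarray,
    config: SimulationConfig,
    total_flow: float,
) -> np.ndarray:
    """Flow through each channel (same unit as ``total_flow``) at each time.

    Conductance-weighted split of the total flow across the parallel section;
    rows sum to ``total_flow`` exactly (mass conservation).
    """
    r_open = _r_open(config)
    frac = open_fractions(channels, t_min)
    g = (r_open * frac ** (-config.k_sim)) ** (-1.0)  # conductances
    return total_flow * g / g.sum(axis=1, keepdims=True)


def _flow_rate(config: SimulationConfig, condition: SampleCondition) -> float:
    if config.flow_rate is not None:
        return config.flow_rate
    gamma = hd.shear_from_gradient(condition.shear_gradient, config.geometry)
    if gamma <= 0:
        raise ConfigError("cannot derive flow: condition has zero shear gradient")
    return hd.flow_for_shear_rate(gamma, config.geometry)


def sample_channel_params(
    condition: SampleCondition,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ChannelOcclusionState]:
    """Draw calibrated per-channel occlusion parameters.

    Onset times are log-normal around a location parameter with coefficient
    of variation ``channel_jitter_cv``; growth widths are proportional to
    onsets (``growth_width_ratio``).  The location is calibrated so the
    noiseless device-level trace yields the condition's target muCT: since
    widths scale with onsets, rescaling the location rescales the whole
    noiseless trace in time, so one fit of a unit-location trace determines
    the location exactly.  Censored conditions get infinite onsets.
    """
    n = config.geometry.n_channels
    target = target_mu_ct(condition, config.dose_response)
    if not math.isfinite(target):
        # still consume the rng so clotting/censored runs stay in step
        rng.standard_normal(n)
        return [
            ChannelOcclusionState(
                onset_time=math.inf, growth_width=math.inf,
                floor_fraction=config.floor_fraction, k_sim=config.k_sim,
            )
            for _ in range(n)
        ]

    cv = config.channel_jitter_cv
    sigma = math.sqrt(math.log1p(cv * cv))
    units = np.exp(sigma * rng.standard_normal(n)) if cv > 0 else np.ones(n)

    def channels_at(scale: float) -> list[ChannelOcclusionState]:
        return [
            ChannelOcclusionState(
                onset_time=scale * u,
                growth_width=config.growth_width_ratio * scale * u,
                floor_fraction=config.floor_fraction,
                k_sim=config.k_sim,
            )
            for u in units
        ]

    # unit-location noiseless trace, truncated where the sensor would saturate
    unit_channels = channels_at(1.0)
    horizon = 5.0 * float(units.max())
    t_unit = np.linspace(1e-3, horizon, 2000)
    r = network_resistance_at(unit_channels, t_unit, config)
    ratio = r / r[0]
    ceiling_ratio = _ceiling_ratio(config, condition)
    cut = np.argmax(ratio > ceiling_ratio)
    if ratio[cut] > ceiling_ratio and cut > 50:
        t_unit, ratio = t_unit[: cut + 1], ratio[: cut + 1]
    trace = PressureTrace(
        times=t_unit * 60.0, pressures=ratio, origin="simulated"
    )
    fit = fit_pressure_trace(trace)
    if not fit.converged:
        raise ConfigError("calibration fit did not converge")
    unit_muct = mu_ct(fit).value
    if not (unit_muct > 0):
        raise ConfigError("calibration produced non-positive unit muCT")
    return channels_at(target / unit_muct)


def _ceiling_ratio(config: SimulationConfig, condition: SampleCondition) -> float:
    """Sensor ceiling expressed as a pressure ratio over the open-network baseline."""
    q = _flow_rate(config, condition) * hd.UL_PER_MIN_TO_M3_PER_S
    n = config.geometry.n_channels
    r_open = _r_open(config)
    r0 = r_open / n * (1.0 + config.series_fraction)
    baseline_kpa = q * r0 / 1000.0
    ceiling_kpa = config.sensor_ceiling_psi * 6.894757
    return max(ceiling_kpa / baseline_kpa, 2.0)


def _noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv <= 0:
        return values.copy()
    sigma = math.sqrt(math.log1p(cv * cv))
    return values * np.exp(sigma * rng.standard_normal(values.size))


def _time_grid(config: SimulationConfig) -> np.ndarray:
    n = int(math.floor(config.duration * 60.0 / config.sample_dt)) + 1
    return np.arange(n) * config.sample_dt  # seconds


def simulate_constant_flow(
    config: SimulationConfig, condition: SampleCondition = SampleCondition()
) -> tuple[PressureTrace, GroundTruth]:
    """Simulate a constant-flow run; return (noisy trace, ground truth).

    At each step: per-channel open fractions -> resistances -> network total;
    dP(t) = Q R_total(t); multiplicative log-normal noise.  The trace is
    truncated with a saturation flag where the noiseless pressure would
    exceed the sensor ceiling.  Ground truth is the fit + muCT of the
    noiseless trace.
    """
    if config.mode != "constant_flow":
        raise ConfigError("config.mode must be 'constant_flow'")
    rng = np.random.default_rng(config.seed)
    channels = sample_channel_params(condition, config, rng)
    q_ul_min = _flow_rate(config, condition)
    q = q_ul_min * hd.UL_PER_MIN_TO_M3_PER_S

    t_s = _time_grid(config)
    r = network_resistance_at(channels, t_s / 60.0, config)
    p_kpa = q * r / 1000.0

    ceiling_kpa = config.sensor_ceiling_psi * 6.894757
    saturated = bool(np.any(p_kpa > ceiling_kpa))
    if saturated:
        cut = int(np.argmax(p_kpa > ceiling_kpa))
        cut = max(cut, 10)  # keep a fittable stub even if saturation is instant
        t_s, p_kpa = t_s[:cut], p_kpa[:cut]

    target = target_mu_ct(condition, config.dose_response)
    noiseless = PressureTrace(
        times=t_s, pressures=p_kpa, flow_rate=q_ul_min,
        condition=condition, origin="simulated", saturated=saturated,
        metadata={"seed": config.seed, "noiseless": True},
    )
    truth_res = analyze_trace(noiseless)
    truth = GroundTruth(
        mu_ct_true=CENSORED if truth_res.censored else truth_res.value,
        censored=truth_res.censored,
        target=target,
        channels=tuple(channels),
        seed=int(config.seed),
        dose_response=config.dose_response,
    )
    trace = noiseless.with_(
        pressures=_noise(p_kpa, config.noise_cv, rng),
        metadata={"seed": config.seed},
    )
    return trace, truth


def simulate_constant_pressure(
    config: SimulationConfig, condition: SampleCondition = SampleCondition()
) -> tuple[FlowTrace, GroundTruth]:
    """Simulate a constant-pressure run: Q(t) = dP / R_total(t), sigmoidal decay.

    ``config.driving_pressure`` (kPa) defaults to 5 kPa.  Ground truth is
    obtained from the equivalent pressure ratio R(t)/R(0), which carries the
    same occlusion information as the constant-flow trace.
    """
    if config.mode != "constant_pressure":
        raise ConfigError("config.mode must be 'constant_pressure'")
    rng = np.random.default_rng(config.seed)
    channels = sample_channel_params(condition, config, rng)
    dp_kpa = config.driving_pressure if config.driving_pressure is not None else 5.0
    if dp_kpa <= 0:
        raise ConfigError("driving_pressure must be positive")

    t_s = _time_grid(config)
    r = network_resistance_at(channels, t_s / 60.0, config)
    q = (dp_kpa * 1000.0) / r / hd.UL_PER_MIN_TO_M3_PER_S  # ul/min

    target = target_mu_ct(condition, config.dose_response)
    ratio_trace = PressureTrace(
        times=t_s, pressures=r / r[0], condition=condition, origin="simulated",
        metadata={"seed": config.seed, "noiseless": True},
    )
    truth_res = analyze_trace(ratio_trace)
    truth = GroundTruth(
        mu_ct_true=CENSORED if truth_res.censored else truth_res.value,
        censored=truth_res.censored,
        target=target,
        channels=tuple(channels),
        seed=int(config.seed),
        dose_response=config.dose_response,
    )
    trace = FlowTrace(
        times=t_s, flows=_noise(q, config.noise_cv, rng),
        driving_pressure=dp_kpa, condition=condition, origin="simulated",
        metadata={"seed": config.seed},
    )
    return trace, truth


def simulate_intensity(
    condition: SampleCondition, config: SimulationConfig
) -> IntensityTrace:
    """Normalized fibrin-intensity trace: logistic growth tied to occlusion.

    Midpoint is the channel-average onset time; additive Gaussian noise
    (sd 0.02) clipped to [0, 1].  Censored conditions give a flat near-zero
    trace.
    """
    rng = np.random.default_rng(config.seed)
    channels = sample_channel_params(condition, config, rng)
    t_min = _time_grid(config) / 60.0
    onsets = [c.onset_time for c in channels if math.isfinite(c.onset_time)]
    if onsets:
        mid = float(np.mean(onsets))
        width = config.growth_width_ratio * mid
        signal = 1.0 / (1.0 + np.exp(np.clip(-(t_min - mid) / width, -500, 500)))
    else:
        signal = np.zeros_like(t_min)
    noisy = np.clip(signal + 0.02 * rng.standard_normal(t_min.size), 0.0, 1.0)
    return IntensityTrace(
        times=t_min, normalized_intensity=noisy, condition=condition,
        metadata={"seed": config.seed},
    )


def simulate_cohort(
    design: Sequence[tuple[SampleCondition, int]],
    config: SimulationConfig,
    out_dir=None,
):
    """Simulate a whole experimental design; return (manifest, traces).

    ``design`` is a sequence of (condition, n_replicates).  Per-run seeds are
    spawned deterministically from ``config.seed``.  With ``out_dir`` set,
    one trace CSV per run plus ``manifest.csv`` and the full config as YAML
    are written there.  The manifest (pandas DataFrame) links run_id, file,
    condition fields, seed and ground truth.
    """
    import pandas as pd

    runs = []
    traces = []
    ss = np.random.SeedSequence(config.seed)
    n_runs = sum(int(reps) for _, reps in design)
    children = ss.spawn(n_runs) if n_runs else []
    i = 0
    for condition, reps in design:
        for rep in range(int(reps)):
            run_seed = int(children[i].generate_state(1)[0] % (2**31))
            run_cfg = replace(config, seed=run_seed)
            if config.mode == "constant_flow":
                trace, truth = simulate_constant_flow(run_cfg, condition)
            else:
                trace, truth = simulate_constant_pressure(run_cfg, condition)
            run_id = f"run{i:04d}"
            runs.append(
                {
                    "run_id": run_id,
                    "file": f"{run_id}.csv",
                    **condition.as_dict(),
                    "replicate": rep,
                    "seed": run_seed,
                    "mu_ct_true_min": truth.mu_ct_true,
                    "censored": truth.censored,
                    "target_mu_ct_min": truth.target,
                }
            )
            traces.append(trace)
            i += 1

    manifest = pd.DataFrame(
        runs,
        columns=[
            "run_id", "file", "heparin", "shear_gradient", "coating", "drug",
            "drug_dose", "disease", "adp", "replicate", "seed",
            "mu_ct_true_min", "censored", "target_mu_ct_min",
        ],
    )
    if manifest["run_id"].duplicated().any():
        raise ConfigError("duplicate run identifiers in design")

    if out_dir is not None:
        from . import io as tfio

        tfio.write_cohort(out_dir, manifest, traces, config)
    return manifest, traces
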