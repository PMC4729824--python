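# thromboflow

Occlusive clot-growth kinetics in a stenosed microfluidic network: pressure-trace
modelling, microfluidic clotting-time extraction, hydraulic-network simulation,
and anticoagulant/platelet-function analytics.

## The problem

Shear-gradient-activated microfluidic haemostasis monitors perfuse whole blood
through a network of parallel stenosed microchannels. Shear-rate gradients at
the stenosis exits activate platelets and trigger clotting; as thrombi occlude
the channels, the hydraulic resistance of the network rises and — under a
constant-flow pump — the inlet pressure climbs. The assay endpoint is a
clotting time read from that pressure trace. This package is for people who
work with such devices (or model them): it provides the pressure model and its
fitting, the endpoint extraction with explicit censoring ("blood did not
clot"), analytic haemodynamics of the channel network, a phenomenological
simulator with known ground truth, and the downstream dose–response,
sensitivity and correlation analyses.

## The model

Thrombus area grows sigmoidally, so the open cross-section of an occluding
channel shrinks as a falling sigmoid and its hydraulic resistance rises as a
power of the lost area. With the Hagen–Poiseuille relation *Q* = ΔP/*R*ₕ under
constant flow, the pressure drop relative to its baseline ΔP₀ follows the
*reciprocal* of a sigmoid,

    ΔP(t) / ΔP₀ = [1 + exp((t − T_g)/(T_s − T_g))]^k ,   k = 1 by default,

parametrized so that **T_g** is the time at which pressure doubles and **T_s**
the time at which it reaches (1 + e)× baseline. The microfluidic clotting time
is canonically

    μCT = (T_g + T_s) / 2 ,

with an alternative threshold definition — the time at which the fitted curve
reaches 2.86× baseline, the midpoint of the two anchor levels (2 + (1+e))/2 ≈
2.86. The two definitions differ slightly by construction (the model passes
1 + √e ≈ 2.65× baseline at the time-average), so every result carries a
mandatory method tag. Runs whose pressure never reaches 1.5× baseline are
censored and excluded from regressions but always counted.

Around the model sit analytic haemodynamics surrogates (wall shear rate
6Q/(wh²) per channel, the fitted linear shear→gradient map with slope
3.49 mm⁻¹, rectangular-duct resistances and their series/parallel network),
and a simulator in which each of the 12 channels occludes logistically with
log-normally jittered onsets, calibrated so the noiseless device-level trace
reproduces a condition-dependent target clotting time: linear in heparin,
exponentially decaying in shear gradient, scaled by coating/drug factors, and
censored for HPS (platelet dense-granule deficiency) unless rescued with ADP.

## Worked example

```python
from thromboflow import (SampleCondition, SimulationConfig,
                         analyze_trace, simulate_constant_flow)

condition = SampleCondition(heparin=0.5, shear_gradient=1225.0)
trace, truth = simulate_constant_flow(SimulationConfig(seed=1), condition)
result = analyze_trace(trace)
print(result.fit.t_g, result.fit.t_s, result.value)
```

Running `python examples/01_fit_single_trace.py` (the same computation with
reporting) prints:

```
simulated 2029 samples at Q = 47.4 ul/min
fitted dP0 = 0.782 kPa, T_g = 18.40 min, T_s = 22.20 min, R^2 = 0.9989
muCT (average of T_g, T_s)     = 20.30 min
muCT (2.86x threshold method)  = 20.76 min
ground truth (noiseless trace) = 20.31 min
```

The pressure doubled at 18.4 min and reached (1+e)× baseline at 22.2 min; the
clotting time of 20.3 min recovers the noiseless ground truth to 0.05% despite
2% multiplicative sensor noise. `examples/03_heparin_dose_response.py` runs
the whole titration design and prints the heparin response
(`muCT = 12.00 + 16.64 × dose, R² = 1.0000`); the other examples cover the
operating map, the shear-gradient sweep, and the platelet-function/censoring
panels.

A thin CLI wraps the same calls for shell pipelines:

```bash
thromboflow simulate out/ --preset heparin-titration --seed 7
thromboflow fit out/
thromboflow dose-response out/ --dose-field heparin
```

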