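# Methods

This note documents the models, the numerical choices and the limits of the
synthetic data, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Pressure model and endpoint

The occlusion model is the reciprocal-sigmoid pressure curve

ΔP(t) = ΔP₀ · [1 + exp((t − T_g)/(T_s − T_g))]^k

with k fixed at 1 by default. The parametrization makes T_g the
pressure-doubling time and T_s the (1+e)× time *for k = 1 only*; free or
fixed k ≠ 1 fitting is opt-in. The "initial pressure" anchoring the ratio is
the fitted baseline parameter ΔP₀ — the model's early-time asymptote — not the
first measured sample; only that choice makes T_g exactly the doubling time in
the model form.

Two endpoint definitions coexist and never mix silently:

* **average** (canonical): μCT = (T_g + T_s)/2. For fits with k ≠ 1 the raw
  parameters lose their level interpretation, so the average method instead
  averages the fitted curve's crossing times of the 2× and (1+e)× levels —
  which reduces exactly to (T_g + T_s)/2 at k = 1 and keeps the endpoint
  insensitive to k (tested: k = 1 vs k = 2 fits agree within a few percent).
* **threshold**: the time the fitted curve reaches a given ratio, default
  2.86 = (2 + (1+e))/2. Note the model evaluated at the *time*-average
  (T_g+T_s)/2 sits at 1 + √e ≈ 2.649; 2.86 is the average of the two pressure
  *levels*. Both conventions appear in the field, hence the mandatory method
  tag on every result.

### Fitting

Ordinary nonlinear least squares (scipy `curve_fit`) on the pressure scale,
parameters (ΔP₀, T_g, d = T_s − T_g), all bounded positive; R² = 1 −
SS_res/SS_tot on the same scale. Initialization is data-driven: ΔP₀ from the
preprocessing baseline (median of the first 10% of samples, minimum 5, after a
3-point median despike), T_g from the first interpolated crossing of 2×
baseline, T_s from the (1+e)× crossing or 1.3 T_g. Up to five deterministic
jittered restarts; a still-failing fit returns `converged=False` rather than
raising.

**Fit window.** Fits use the trace prefix up to 4× the estimated baseline
(`max_fit_ratio`, configurable; `None` fits everything). The endpoint needs
less than a 3-fold rise, and beyond a few-fold rise the trace is governed by
near-total occlusion and sensor saturation, not the growth kinetics the model
describes. On the pressure scale this windowing also prevents the exponential
tail from swamping the baseline region of the least-squares problem, which is
what de-anchors ΔP₀ between different exponents k; with the window the
extracted μCT is k-insensitive. The cap (4) sits just above the highest model
anchor level (1 + e ≈ 3.72) and the default threshold 2.86.

**Censoring.** A run whose maximum pressure never reaches 1.5× baseline over
the whole (unwindowed) trace is censored — below the doubling level with
margin for multiplicative noise. Censored runs yield an endpoint flagged
`censored`, never enter regressions, and are always counted.

## Haemodynamics surrogates

The device-level CFD is replaced by closed forms: wall shear per channel from
the parallel-plate formula γ = 6Q/(wh²) with an explicit `calibration_factor`
(default 1, transparent physics; the constant `REFERENCE_DEVICE_SHEAR_FACTOR
= 2.25` reproduces the reference device's reported 150 µl/min ↔ 2500 s⁻¹
operating map, whose underlying formula is not public); a linear shear →
shear-gradient map with fitted slope 3.49 mm⁻¹; rectangular-duct laminar
resistance from the standard series solution truncated at 20 odd terms
(relative truncation error ≪ 10⁻⁸ at these aspect ratios); stenosis severity
as percent diameter reduction; Newtonian (0.004 Pa·s) or user-supplied
power-law viscosity. No velocity fields, no cell-scale rheology.

## Simulator

Per channel, open area falls logistically from 1 to a floor (0.02) with
midpoint τᵢ and width 0.2 τᵢ; channel resistance scales as a⁻ᵏˢⁱᵐ with
k_sim = 2 (lubrication-type default, deliberately distinct from the fitting
exponent k = 1 so that recovery tests exercise model misspecification).
Twelve channels in parallel plus series elements at 5% of the open-network
resistance (wide reservoirs/tubing contribute little). Constant-flow mode
reports ΔP(t) = Q·R(t), truncated with a saturation flag where the noiseless
pressure would exceed the 12 p.s.i. sensor ceiling; constant-pressure mode
reports Q(t) = ΔP/R(t). Noise is multiplicative log-normal with cv 2% —
pressure sensors err proportionally to scale; the magnitude is a modelling
choice and configurable.

**Condition → target clotting time.** μCT* = (β₀ + β₁·heparin)·exp(−G/G₀) +
μ_floor with defaults β₀ = 12 min, β₁ = 25 min per IU/ml, G₀ = 3000 s⁻¹ mm⁻¹,
μ_floor = 4 min, then × 0.45 for collagen coating, × (1 + 0.05·dose) for
abciximab (µg/ml), × 1.6 for chronic aspirin+clopidogrel. These defaults
place simulated endpoints in the device's working range (roughly 4–40 min
across the presets) and embed exactly the linear-in-heparin and
exponential-in-gradient structure the analytics are meant to recover; they
are config values, not claims about any particular dataset. HPS samples are
censored below 7.5 µM ADP; above it the rescued clotting time is
8.5 − 1.2·(ADP − 7.5) min, floored at 2 min — decreasing in ADP, matching the
qualitative rescue pattern and magnitudes of reported patient panels.

**Calibration and ground truth.** Onsets are drawn log-normally (cv 0.15 —
per-channel heterogeneity is not quantified anywhere; this is a modelling
choice) around a location calibrated so the *noiseless* device trace yields
the target μCT. Because widths are proportional to onsets, rescaling the
location rescales the whole noiseless trace in time; the location is
therefore solved in closed form from a single fit of a unit-location trace
(scale = target/μCT_unit) — exact and deterministic, no iterative search.
Ground truth is operational: the same fit + extraction applied to the
noiseless trace. Recovery error against it therefore measures noise and
fitting alone, not the (deliberate) mismatch between the logistic-network
curve and the k = 1 model family.

**What the generator does not emulate.** No coagulation biochemistry, no
embolization/detachment, no red-cell sedimentation, no inter-donor biological
variance, no baseline drift or non-multiplicative sensor artefacts. Passing
recovery tests show the pipeline is consistent and noise-robust under the
stated noise model; they do not certify accuracy on real blood.

## Analytics

Linear dose–response by OLS (scipy `linregress`; slope CI from the t
distribution with n − 2 df); exponential shear response A·exp(−G/G₀) + c by
bounded least squares, offset free by default (the canonical functional form
does not pin it) with an optional zero pin; a fit whose decay scale exceeds
100× the gradient span is flagged degenerate. Sensitivity = slope of the
fold-change (relative to the baseline dose) against dose, which makes assays
with different native units comparable. Pearson r via scipy; constant series
are reported not-computable. Censored endpoints are excluded from every fit
and correlation but counted in `censored_excluded`. Group-significance
annotations (t-tests/ANOVA) are left to standard tools; they depend on
biological replicate structure the simulator does not model.

## Problem sizes and determinism

Default traces sample at 1 s for 60 min (≈ 2000–3600 points after
saturation truncation); the goodness-of-fit survey uses a 5 × 4 heparin ×
gradient grid with 3 seeds per cell (60 runs); the dose–response designs use
6 conditions × 3 replicates. Identical config + seed reproduce all outputs
bit-identically (per-run seeds are spawned from the cohort seed via numpy
`SeedSequence`). μCT is insensitive to the occlusion floor (< 1% when the
floor is halved) because the fit window ends long before the floor binds.

## Known limitations

* The general-k model form is a reconstruction; only k = 1 carries the exact
  T_g/T_s level interpretation, and k ≠ 1 endpoints are defined via curve
  crossings as described above.
* The parallel-plate shear estimate underestimates the reference device's
  printed operating map by ≈ 2.25×; the discrepancy is exposed, not hidden,
  via `calibration_factor`.
* Dose–response defaults are order-of-magnitude calibrations; any real
  device requires its own calibration of β₀, β₁, G₀, μ_floor and the
  coating/drug factors.
* Censoring is binary (clot / no clot within the run); no survival-style
  partial information is extracted from censored traces.
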