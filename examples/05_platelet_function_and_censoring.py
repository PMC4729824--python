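"""Platelet-function panels: drug responses, censoring, and assay ranking.

Three screens on collagen-coated channels at a gradient of 4,375 s^-1 mm^-1:

* abciximab (anti-alphaIIb/beta3) dose series — clotting time rises with dose;
* Hermansky-Pudlak syndrome (HPS) panel — dense-granule-deficient blood
  never clots ("censored") unless rescued with exogenous ADP, and higher
  ADP shortens the rescued clotting time;
* cross-assay sensitivity — fold-change slope versus heparin dose ranks the
  microfluidic clotting time against ACT/aPTT-like readouts.
"""
from thromboflow import SimulationConfig, analyze_trace, assay_sensitivity, simulate_cohort
from thromboflow.presets import cohort_design, simulated_assay_panel

print("abciximab dose series (collagen, 4,375 s^-1 mm^-1):")
manifest, traces = simulate_cohort(
    cohort_design("abciximab-dose"), SimulationConfig(seed=11)
)
results = [analyze_trace(t) for t in traces]
for dose, grp in manifest.assign(m=[r.value for r in results]).groupby("drug_dose"):
    print(f"  {dose:4.0f} ug/ml -> muCT {grp['m'].mean():5.2f} min")

print("\nHPS / ADP rescue panel:")
manifest, traces = simulate_cohort(cohort_design("hps-adp"),
                                   SimulationConfig(seed=12, duration=25.0))
results = [analyze_trace(t) for t in traces]
rows = manifest.assign(m=[r.value for r in results], cen=[r.censored for r in results])
for (g, adp), grp in rows.groupby(["shear_gradient", "adp"]):
    if grp["cen"].all():
        print(f"  gradient {g:5,.0f}, ADP {adp:4.1f} uM -> did not clot "
              f"(censored, n={len(grp)})")
    else:
        print(f"  gradient {g:5,.0f}, ADP {adp:4.1f} uM -> muCT "
              f"{grp['m'].mean():5.2f} min")

print("\ncross-assay sensitivity (fold change per IU/kg heparin):")
panel = simulated_assay_panel(seed=3)
for name in ("muct", "act", "aptt"):
    s = assay_sensitivity(panel["doses"], panel[name], assay_name=name)
    print(f"  {name:5s} slope = {s.slope:.4f} per IU/kg (R^2 = {s.r_squared:.3f})")
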