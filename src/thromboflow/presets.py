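"""Preset experimental designs.

Each preset returns a cohort design — a list of (SampleCondition,
n_replicates) — matching the assay's canonical validation experiments:
heparin titrations at fixed shear gradient, shear-gradient sweeps at fixed
heparin, anti-platelet dose series on collagen, HPS/ADP rescue panels, and
the heparin-by-gradient model-validation grid.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .conditions import SampleCondition

__all__ = ["PRESETS", "cohort_design", "simulated_assay_panel"]

#: standard replicate count per condition (three donors/runs per condition)
DEFAULT_REPLICATES = 3


def _grid(conditions, replicates=DEFAULT_REPLICATES):
    return [(c, replicates) for c in conditions]


def heparin_titration(gradient: float = 1225.0, replicates: int = DEFAULT_REPLICATES):
    """Heparin 0-1 IU/ml at a fixed shear gradient (linear muCT response)."""
    doses = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)
    return _grid(
        [SampleCondition(heparin=h, shear_gradient=gradient) for h in doses],
        replicates,
    )


def shear_sweep(heparin: float = 0.25, replicates: int = DEFAULT_REPLICATES):
    """Gradient sweep 262-8750 s^-1 mm^-1 at fixed heparin (exponential decay)."""
    gradients = (262.0, 525.0, 1225.0, 2625.0, 5250.0, 8750.0)
    return _grid(
        [SampleCondition(heparin=heparin, shear_gradient=g) for g in gradients],
        replicates,
    )


def model_grid(replicates: int = DEFAULT_REPLICATES):
    """Heparin x shear-gradient grid for model goodness-of-fit surveys."""
    heparins = (0.0, 0.25, 0.5, 0.75, 1.0)
    gradients = (525.0, 1225.0, 2625.0, 5250.0)
    return _grid(
        [
            SampleCondition(heparin=h, shear_gradient=g)
            for h in heparins
            for g in gradients
        ],
        replicates,
    )


def heparin_validation(replicates: int = DEFAULT_REPLICATES):
    """Four-dose heparin series at 1225 s^-1 mm^-1 (model validation design)."""
    return _grid(
        [
            SampleCondition(heparin=h, shear_gradient=1225.0)
            for h in (0.0, 0.1, 0.5, 1.0)
        ],
        replicates,
    )


def shear_validation(replicates: int = DEFAULT_REPLICATES):
    """Four-gradient series at heparin 0.5 IU/ml (model validation design)."""
    return _grid(
        [
            SampleCondition(heparin=0.5, shear_gradient=g)
            for g in (525.0, 1225.0, 2625.0, 5250.0)
        ],
        replicates,
    )


def abciximab_dose(replicates: int = DEFAULT_REPLICATES):
    """Abciximab 0/5/20 ug/ml in collagen-coated channels at 4375 s^-1 mm^-1."""
    return _grid(
        [
            SampleCondition(
                shear_gradient=4375.0, coating="collagen",
                drug="abciximab", drug_dose=d,
            )
            for d in (0.0, 5.0, 20.0)
        ],
        replicates,
    )


def aspirin_plavix(replicates: int = DEFAULT_REPLICATES):
    """Healthy vs chronic aspirin+clopidogrel, collagen, 4375 s^-1 mm^-1."""
    return _grid(
        [
            SampleCondition(shear_gradient=4375.0, coating="collagen"),
            SampleCondition(
                shear_gradient=4375.0, coating="collagen", drug="aspirin_plavix"
            ),
        ],
        replicates,
    )


def hps_adp(replicates: int = DEFAULT_REPLICATES):
    """HPS ADP-rescue panel: censored below 7.5 uM ADP, rescued above."""
    conditions = [
        SampleCondition(disease="hps", coating="collagen", shear_gradient=4375.0, adp=a)
        for a in (0.0, 1.0, 5.0, 7.5, 10.0)
    ]
    conditions.append(
        SampleCondition(disease="hps", coating="collagen", shear_gradient=8750.0, adp=0.0)
    )
    return _grid(conditions, replicates)


PRESETS = {
    "heparin-titration": heparin_titration,
    "shear-sweep": shear_sweep,
    "model-grid": model_grid,
    "heparin-validation": heparin_validation,
    "shear-validation": shear_validation,
    "abciximab-dose": abciximab_dose,
    "aspirin-plavix": aspirin_plavix,
    "hps-adp": hps_adp,
}


def cohort_design(name: str, **kwargs):
    """Look up a preset design by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return factory(**kwargs)


def simulated_assay_panel(
    doses: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 150.0),
    seed: int = 0,
    muct_slope: float = 0.03,
    act_slope: float = 0.012,
    aptt_slope: float = 0.006,
    noise_cv: float = 0.05,
) -> dict:
    """Synthetic cross-assay comparison: three readouts of one heparin series.

    Returns {"doses": ..., "muct": ..., "act": ..., "aptt": ...} where each
    readout rises linearly on the fold-change scale with its embedded
    sensitivity slope (per IU kg^-1) and multiplicative noise.  The muCT
    readout is constructed steeper, so fold-change sensitivity ranking is
    well-defined for tests and examples; the clinical-assay readouts are
    configurable linear stand-ins, not assay simulations.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)

    def readout(baseline: float, slope: float) -> np.ndarray:
        clean = baseline * (1.0 + slope * doses)
        return clean * (1.0 + noise_cv * rng.standard_normal(doses.size))

    return {
        "doses": doses,
        "muct": readout(4.25, muct_slope),     # min
        "act": readout(120.0, act_slope),      # s
        "aptt": readout(32.0, aptt_slope),     # s
    }
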