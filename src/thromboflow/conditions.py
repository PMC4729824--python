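"""Sample conditions: the biological/pharmacological state of a blood sample.

A :class:`SampleCondition` records everything the assay varies about the
blood itself — anticoagulant dose, the haemodynamic operating point
(wall-shear-rate gradient), channel surface coating, anti-platelet drug,
disease state and ADP supplementation.  It travels with every trace as
metadata and is the ground-truth handle for the synthetic-data generator.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import InvalidParameterError

COATINGS = ("bare", "collagen")
DRUGS = ("none", "abciximab", "aspirin_plavix")
DISEASES = ("healthy", "hps")


@dataclass(frozen=True)
class SampleCondition:
    """State of a blood sample and its perfusion operating point.

    Parameters
    ----------
    heparin:
        Unfractionated heparin concentration, IU ml^-1.
    shear_gradient:
        Wall shear-rate gradient at the stenosis exit, s^-1 mm^-1.  This is
        the haemodynamic activator of clotting; higher gradients clot faster.
    coating:
        Channel surface: ``"bare"`` PDMS or ``"collagen"`` (platelet agonist,
        shortens clotting times).
    drug:
        Anti-platelet treatment: ``"none"``, ``"abciximab"`` (dose-dependent,
        see ``drug_dose``) or ``"aspirin_plavix"`` (chronic dual therapy).
    drug_dose:
        Abciximab dose, ug ml^-1 (ignored for other drugs).
    disease:
        ``"healthy"`` or ``"hps"`` (Hermansky-Pudlak syndrome: platelet
        dense-granule deficiency; blood does not clot in the device unless
        rescued with exogenous ADP).
    adp:
        Exogenous ADP supplementation, uM.
    """

    heparin: float = 0.0
    shear_gradient: float = 1225.0
    coating: str = "bare"
    drug: str = "none"
    drug_dose: float = 0.0
    disease: str = "healthy"
    adp: float = 0.0

    def __post_init__(self) -> None:
        if self.heparin < 0 or self.drug_dose < 0 or self.adp < 0:
            raise InvalidParameterError("doses must be non-negative")
        if self.shear_gradient < 0:
            raise InvalidParameterError("shear_gradient must be non-negative")
        if self.coating not in COATINGS:
            raise InvalidParameterError(f"coating must be one of {COATINGS}")
        if self.drug not in DRUGS:
            raise InvalidParameterError(f"drug must be one of {DRUGS}")
        if self.disease not in DISEASES:
            raise InvalidParameterError(f"disease must be one of {DISEASES}")

    def as_dict(self) -> dict:
        return asdict(self)
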