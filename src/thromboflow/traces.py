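"""Timestamped sensor traces.

Three series types cover the device's readouts:

* :class:`PressureTrace` — inlet pressure vs time under constant flow; the
  fit target for the occlusion model.  Times in seconds, pressures in kPa
  (p.s.i. input is converted on construction when ``unit="psi"``).
* :class:`FlowTrace` — flow vs time under constant driving pressure.
* :class:`IntensityTrace` — normalized fibrin fluorescence vs time, used to
  establish the sigmoidal occlusion kinetics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .conditions import SampleCondition
from .errors import TraceInputError

#: exact conversion, 1 p.s.i. in kPa
PSI_TO_KPA = 6.894757

#: minimum number of samples a trace must have before model fitting
MIN_FIT_SAMPLES = 10


def _validated_series(times, values, name: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
        raise TraceInputError(f"{name}: times and values must be 1-D and equal length")
    if t.size < 2:
        raise TraceInputError(f"{name}: at least 2 samples required")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
        raise TraceInputError(f"{name}: non-finite samples")
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise TraceInputError(f"{name}: times must be strictly increasing (row {row})")
    return t, v


@dataclass(frozen=True)
class PressureTrace:
    """Pressure-vs-time series from the inline sensor (constant-flow mode).

    ``times`` are seconds from the start of perfusion; ``pressures`` are kPa.
    Pass ``unit="psi"`` to convert raw p.s.i. readings on construction (the
    original unit is kept in ``source_unit``).
    """

    times: np.ndarray
    pressures: np.ndarray
    flow_rate: Optional[float] = None  # ul min^-1, constant-flow mode
    condition: Optional[SampleCondition] = None
    origin: str = "measured"  # measured | simulated
    unit: str = "kpa"
    saturated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, p = _validated_series(self.times, self.pressures, "PressureTrace")
        if np.any(p <= 0):
            raise TraceInputError("PressureTrace: pressures must be positive")
        if self.unit not in ("kpa", "psi"):
            raise TraceInputError(f"unknown pressure unit {self.unit!r}")
        source_unit = self.unit
        if self.unit == "psi":
            p = p * PSI_TO_KPA
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "unit", "kpa")
        md = dict(self.metadata)
        md.setdefault("source_unit", source_unit)
        object.__setattr__(self, "metadata", md)

    def __len__(self) -> int:
        return self.times.size

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0

    def with_(self, **kwargs) -> "PressureTrace":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FlowTrace:
    """Flow-vs-time series (constant-pressure mode).

    ``times`` in seconds, ``flows`` in ul min^-1, ``driving_pressure`` in kPa.
    """

    times: np.ndarray
    flows: np.ndarray
    driving_pressure: Optional[float] = None  # kPa
    condition: Optional[SampleCondition] = None
    origin: str = "measured"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, q = _validated_series(self.times, self.flows, "FlowTrace")
        if np.any(q < 0):
            raise TraceInputError("FlowTrace: flows must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)

    def __len__(self) -> int:
        return self.times.size

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0


@dataclass(frozen=True)
class IntensityTrace:
    """Normalized fibrin fluorescence I(t)/I_max vs time (minutes).

    The normalization divisor is the intensity of a fully clotted region, so
    values live in [0, 1] up to noise; raw values are retained (clipping, if
    wanted for display, is the caller's choice).
    """

    times: np.ndarray  # minutes
    normalized_intensity: np.ndarray
    condition: Optional[SampleCondition] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, i = _validated_series(self.times, self.normalized_intensity, "IntensityTrace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "normalized_intensity", i)

    def __len__(self) -> int:
        return self.times.size
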