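"""Dose-response, sensitivity and correlation analytics on muCT endpoints.

Censoring convention: censored runs ("blood did not clot") never enter a
regression or correlation, but are always counted and reported — mirroring
how non-clotting samples are tabulated alongside finite clotting times.
Inputs may be :class:`~thromboflow.clot_model.MuCTResult` objects, plain
floats (inf/nan = censored), or a mixture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .clot_model import MuCTResult
from .errors import InvalidParameterError

__all__ = [
    "DoseResponseFit",
    "SensitivityResult",
    "CorrelationResult",
    "linear_dose_response",
    "exponential_shear_response",
    "fold_change",
    "assay_sensitivity",
    "pearson_correlation",
]


def _values(mu_cts: Sequence) -> np.ndarray:
    """Extract float endpoints; censored -> nan."""
    out = []
    for m in mu_cts:
        if isinstance(m, MuCTResult):
            out.append(float("nan") if m.censored else m.value)
        else:
            v = float(m)
            out.append(float("nan") if math.isinf(v) else v)
    return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted dose-response curve (linear or exponential decay).

    Linear:  y = intercept + slope * x.
    Exponential decay: y = amplitude * exp(-x / decay_scale) + offset.
    ``censored_excluded`` counts observations dropped for censoring;
    ``converged=False`` flags insufficient data or a failed/degenerate fit
    (``note`` says which).
    """

    kind: str  # "linear" | "exponential_decay"
    r_squared: float
    n_points: int
    censored_excluded: int
    converged: bool
    slope: Optional[float] = None
    intercept: Optional[float] = None
    slope_stderr: Optional[float] = None
    amplitude: Optional[float] = None
    decay_scale: Optional[float] = None
    offset: Optional[float] = None
    note: Optional[str] = None

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the linear slope (t distribution, n-2 df)."""
        if self.kind != "linear" or not self.converged:
            raise InvalidParameterError("slope CI only for converged linear fits")
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n_points - 2)
        return (self.slope - tcrit * self.slope_stderr,
                self.slope + tcrit * self.slope_stderr)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.intercept + self.slope * x
        return self.amplitude * np.exp(-x / self.decay_scale) + self.offset


def _failed(kind: str, n: int, excluded: int, note: str) -> DoseResponseFit:
    return DoseResponseFit(
        kind=kind, r_squared=float("nan"), n_points=n,
        censored_excluded=excluded, converged=False, note=note,
    )


def linear_dose_response(doses: Sequence[float], mu_cts: Sequence) -> DoseResponseFit:
    """Ordinary least squares muCT = a + b * dose.

    Censored results are excluded (counted in ``censored_excluded``); fewer
    than 3 uncensored points gives an insufficient-data result rather than
    an exception.
    """
    x = np.asarray(doses, dtype=float)
    y = _values(mu_cts)
    if x.size != y.size:
        raise InvalidParameterError("doses and muCTs must have equal length")
    keep = np.isfinite(y)
    excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        return _failed("linear", int(x.size), excluded, "fewer than 3 uncensored points")
    if np.ptp(x) == 0:
        return _failed("linear", int(x.size), excluded, "constant dose")
    res = stats.linregress(x, y)
    return DoseResponseFit(
        kind="linear", slope=float(res.slope), intercept=float(res.intercept),
        slope_stderr=float(res.stderr), r_squared=float(res.rvalue**2),
        n_points=int(x.size), censored_excluded=excluded, converged=True,
    )


def exponential_shear_response(
    gradients: Sequence[float],
    mu_cts: Sequence,
    pin_offset: bool = False,
) -> DoseResponseFit:
    """Least-squares fit muCT = A exp(-G / G0) + c over shear gradients G.

    The offset ``c`` is free by default (``pin_offset=True`` fixes it at 0).
    Requires >= 4 uncensored points; constant input or non-convergence is
    flagged, never raised.
    """
    g = np.asarray(gradients, dtype=float)
    y = _values(mu_cts)
    if g.size != y.size:
        raise InvalidParameterError("gradients and muCTs must have equal length")
    keep = np.isfinite(y)
    excluded = int((~keep).sum())
    g, y = g[keep], y[keep]
    if g.size < 4:
        return _failed("exponential_decay", int(g.size), excluded,
                       "fewer than 4 uncensored points")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0 or np.ptp(g) == 0:
        return _failed("exponential_decay", int(g.size), excluded,
                       "degenerate (constant) input")

    span = float(np.ptp(g))
    amp0 = max(float(y.max() - y.min()), 1e-9)
    c0 = float(y.min())

    if pin_offset:
        def model(gg, a, g0):
            return a * np.exp(-gg / g0)
        p0, lo, hi = [amp0 + c0, span / 2.0], [1e-12, 1e-9], [np.inf, np.inf]
    else:
        def model(gg, a, g0, c):
            return a * np.exp(-gg / g0) + c
        p0 = [amp0, span / 2.0, c0]
        lo, hi = [1e-12, 1e-9, -np.inf], [np.inf, np.inf, np.inf]

    try:
        popt, _ = optimize.curve_fit(
            model, g, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return _failed("exponential_decay", int(g.size), excluded, "fit failure")
    ssr = float(np.sum((model(g, *popt) - y) ** 2))
    decay = float(popt[1])
    note = None
    if decay > 100.0 * span:
        note = "degenerate: decay scale >> gradient span (near-constant response)"
    return DoseResponseFit(
        kind="exponential_decay",
        amplitude=float(popt[0]), decay_scale=decay,
        offset=0.0 if pin_offset else float(popt[2]),
        r_squared=1.0 - ssr / sst, n_points=int(g.size),
        censored_excluded=excluded, converged=True, note=note,
    )


def fold_change(values: Sequence[float], baseline_index: int = 0) -> np.ndarray:
    """Element-wise values / values[baseline_index]; signs preserved."""
    v = np.asarray(values, dtype=float)
    base = v[baseline_index]
    if base == 0:
        raise InvalidParameterError("baseline value must be nonzero")
    return v / base


@dataclass(frozen=True)
class SensitivityResult:
    """Assay sensitivity: slope of fold-change (vs baseline) against dose.

    Fold-change normalization makes the slope unit-free in the readout, so
    assays with different native units rank on a common scale.
    """

    assay_name: str
    slope: float
    intercept: float
    r_squared: float
    dose_units: str
    n_points: int
    converged: bool = True


def assay_sensitivity(
    doses: Sequence[float],
    values: Sequence[float],
    baseline_index: int = 0,
    assay_name: str = "assay",
    dose_units: str = "IU kg^-1",
) -> SensitivityResult:
    """Fold-change against the baseline dose, then linear regression on dose.

    The slope is the assay's sensitivity (fold change per dose unit).
    """
    fc = fold_change(values, baseline_index)
    fit = linear_dose_response(doses, fc)
    if not fit.converged:
        return SensitivityResult(
            assay_name=assay_name, slope=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), dose_units=dose_units,
            n_points=fit.n_points, converged=False,
        )
    return SensitivityResult(
        assay_name=assay_name, slope=fit.slope, intercept=fit.intercept,
        r_squared=fit.r_squared, dose_units=dose_units,
        n_points=fit.n_points,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of an assay endpoint with a biomarker series."""

    r: float
    n: int
    pair: tuple[str, str]
    computable: bool = True


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Standard Pearson r; constant input is reported as not computable."""
    xv = _values(x)
    yv = _values(y)
    if xv.size != yv.size:
        raise InvalidParameterError("series must have equal length")
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise InvalidParameterError("need at least 3 paired finite observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(r=float("nan"), n=int(xv.size), pair=pair,
                                 computable=False)
    r = stats.pearsonr(xv, yv).statistic
    return CorrelationResult(r=float(r), n=int(xv.size), pair=pair)
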