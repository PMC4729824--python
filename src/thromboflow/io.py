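"""Plain-text file formats: trace CSV, manifest CSV, fit JSON, config YAML.

Trace CSV dialect
-----------------
Header ``time_s,pressure_kpa`` (or ``pressure_psi``, converted on read) for
pressure traces, ``time_s,flow_ul_min`` for flow traces; optional leading
comment lines ``# key=value`` carry acquisition metadata (flow_ul_min,
heparin_iu_ml, shear_gradient_s1_mm1, coating, drug, drug_dose, disease,
adp_um, seed, origin, saturated, driving_pressure_kpa).  Round trips are
lossless for values and metadata.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .clot_model import ClotModelFit, MuCTResult
from .conditions import SampleCondition
from .errors import TraceParseError
from .traces import FlowTrace, PressureTrace

__all__ = [
    "read_trace",
    "write_trace",
    "write_fit_json",
    "read_fit_json",
    "write_cohort",
    "read_manifest",
    "config_hash",
]

_CONDITION_KEYS = {
    "heparin_iu_ml": "heparin",
    "shear_gradient_s1_mm1": "shear_gradient",
    "coating": "coating",
    "drug": "drug",
    "drug_dose_ug_ml": "drug_dose",
    "disease": "disease",
    "adp_um": "adp",
}


def _condition_comments(c: SampleCondition) -> list[str]:
    vals = c.as_dict()
    return [f"# {k}={vals[v]}" for k, v in _CONDITION_KEYS.items()]


def write_trace(path: Union[str, Path], trace: Union[PressureTrace, FlowTrace]) -> Path:
    """Write a trace as CSV with ``# key=value`` metadata comments."""
    path = Path(path)
    lines = [f"# origin={trace.origin}"]
    if trace.condition is not None:
        lines += _condition_comments(trace.condition)
    for k, v in trace.metadata.items():
        lines.append(f"# {k}={v}")
    if isinstance(trace, PressureTrace):
        if trace.flow_rate is not None:
            lines.append(f"# flow_ul_min={trace.flow_rate!r}")
        lines.append(f"# saturated={trace.saturated}")
        lines.append("time_s,pressure_kpa")
        cols = zip(trace.times, trace.pressures)
    else:
        if trace.driving_pressure is not None:
            lines.append(f"# driving_pressure_kpa={trace.driving_pressure!r}")
        lines.append("time_s,flow_ul_min")
        cols = zip(trace.times, trace.flows)
    lines += [f"{t:.9g},{v:.9g}" for t, v in cols]
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_meta(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        f = float(value)
        return int(f) if f.is_integer() and "." not in value and "e" not in low else f
    except ValueError:
        return value


def read_trace(path: Union[str, Path]) -> Union[PressureTrace, FlowTrace]:
    """Read a trace CSV; p.s.i. pressures are converted to kPa on read."""
    path = Path(path)
    meta: dict = {}
    header = None
    data_t, data_v = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = _parse_meta(v.strip())
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceParseError(f"{path}: malformed row {lineno}: {raw!r}")
        try:
            data_t.append(float(parts[0]))
            data_v.append(float(parts[1]))
        except ValueError as exc:
            raise TraceParseError(f"{path}: non-numeric row {lineno}: {raw!r}") from exc

    if header is None:
        raise TraceParseError(f"{path}: no header row")
    if header[0] != "time_s" or len(header) != 2:
        raise TraceParseError(
            f"{path}: expected columns time_s,<pressure_kpa|pressure_psi|flow_ul_min>,"
            f" got {header}"
        )
    t = np.asarray(data_t)
    v = np.asarray(data_v)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TraceParseError(
            f"{path}: time not strictly increasing at data row {int(bad[0]) + 2}"
        )

    cond_vals = {attr: meta.pop(k) for k, attr in _CONDITION_KEYS.items() if k in meta}
    condition = SampleCondition(**cond_vals) if cond_vals else None
    origin = str(meta.pop("origin", "measured"))

    value_col = header[1]
    if value_col in ("pressure_kpa", "pressure_psi"):
        flow = meta.pop("flow_ul_min", None)
        saturated = bool(meta.pop("saturated", False))
        return PressureTrace(
            times=t, pressures=v,
            unit="psi" if value_col == "pressure_psi" else "kpa",
            flow_rate=None if flow is None else float(flow),
            condition=condition, origin=origin, saturated=saturated, metadata=meta,
        )
    if value_col == "flow_ul_min":
        dp = meta.pop("driving_pressure_kpa", None)
        return FlowTrace(
            times=t, flows=v,
            driving_pressure=None if dp is None else float(dp),
            condition=condition, origin=origin, metadata=meta,
        )
    raise TraceParseError(f"{path}: unknown value column {value_col!r}")


def _jsonable(x):
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return x


def write_fit_json(
    path: Union[str, Path],
    fit: Optional[ClotModelFit],
    result: MuCTResult,
    extra: Optional[dict] = None,
) -> Path:
    """Write fit parameters + muCT endpoint as JSON (censored runs have no fit)."""
    from . import __version__

    path = Path(path)
    payload = {
        "tool_version": __version__,
        "censored": result.censored,
        "mu_ct_min": _jsonable(result.value) if not result.censored else None,
        "method": result.method,
        "threshold_ratio": result.threshold_ratio,
    }
    if fit is not None:
        payload.update(
            P0=fit.p0, T_g_min=fit.t_g, T_s_min=fit.t_s, k=fit.k,
            r_squared=fit.r_squared, converged=fit.converged,
            n_points=fit.n_points,
        )
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_fit_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config) -> str:
    """Short sha256 of a config (dataclass or mapping), for provenance."""
    obj = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_cohort(out_dir, manifest: pd.DataFrame, traces, config) -> Path:
    """Write one trace CSV per run plus manifest.csv and the config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for row, trace in zip(manifest.itertuples(index=False), traces):
        write_trace(out / row.file, trace)
    manifest.to_csv(out / "manifest.csv", index=False)
    cfg = asdict(config) if is_dataclass(config) else dict(config)
    cfg["config_hash"] = config_hash(config)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort manifest; run_ids must be unique, files must exist."""
    path = Path(path)
    df = pd.read_csv(path)
    if "run_id" not in df.columns or "file" not in df.columns:
        raise TraceParseError(f"{path}: manifest needs run_id and file columns")
    if df["run_id"].duplicated().any():
        raise TraceParseError(f"{path}: duplicate run_ids")
    missing = [f for f in df["file"] if not (path.parent / f).exists()]
    if missing:
        raise TraceParseError(f"{path}: missing trace files: {missing[:3]}")
    return df
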