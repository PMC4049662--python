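"""CSV/JSON readers and writers for observations, curves and fit results.

Formats are plain text and diff friendly: CSV tables with ``#``-prefixed
comment headers carrying metadata (time unit, generator seed, truth
parameters), JSON for fit and joining reports.  Numeric values round-trip
to at least 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fitting import FitResult, Observations
from .growth import GrowthCurve

__all__ = [
    "read_observations", "write_observations",
    "read_curve", "write_curve",
    "write_fit_result", "read_fit_result",
]

_FLOAT_FMT = "%.17g"

OBS_COLUMNS = ("time", "volume", "include")
CURVE_COLUMNS = ("time", "volume", "growth_ratio", "active_fraction")


def _read_comments(path: Path) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_observations(path) -> Observations:
    """Read an observations CSV (columns time, volume, include)."""
    path = Path(path)
    meta = _read_comments(path)
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, ("time", "volume"), path)
    for col in ("time", "volume"):
        if not np.issubdtype(frame[col].dtype, np.number):
            raise SchemaError(f"{path}: column {col} contains non-numeric cells")
    include = (frame["include"].astype(bool).to_numpy()
               if "include" in frame.columns else None)
    cv = float(meta.get("assumed_cv", 0.05))
    return Observations(time=frame["time"].to_numpy(dtype=float),
                        volume=frame["volume"].to_numpy(dtype=float),
                        include=include, assumed_cv=cv)


def write_observations(obs: Observations, path,
                       metadata: Optional[Dict[str, object]] = None) -> None:
    """Write observations with optional truth metadata in comment lines."""
    path = Path(path)
    lines = [f"# assumed_cv={obs.assumed_cv!r}"]
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}={val!r}")
    frame = pd.DataFrame({"time": obs.time, "volume": obs.volume,
                          "include": obs.include.astype(int)})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_curve(path) -> GrowthCurve:
    """Read a growth-curve CSV written by :func:`write_curve`."""
    path = Path(path)
    meta = _read_comments(path)
    frame = pd.read_csv(path, comment="#")
    _require_columns(frame, CURVE_COLUMNS, path)
    if "v_max" not in meta:
        raise SchemaError(f"{path}: missing '# v_max=' metadata line")
    return GrowthCurve(
        time=frame["time"].to_numpy(dtype=float),
        volume=frame["volume"].to_numpy(dtype=float),
        growth_ratio=frame["growth_ratio"].to_numpy(dtype=float),
        active_fraction=frame["active_fraction"].to_numpy(dtype=float),
        v_max=float(meta["v_max"]),
        time_unit=meta.get("time_unit", "model"),
    )


def write_curve(curve: GrowthCurve, path,
                metadata: Optional[Dict[str, object]] = None) -> None:
    path = Path(path)
    lines = [f"# time_unit={curve.time_unit}", f"# v_max={curve.v_max!r}"]
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}={val!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        curve.to_frame().to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_fit_result(result: FitResult, path,
                     extra: Optional[Dict[str, object]] = None) -> None:
    """Serialize a fit result (plus a config echo / input digest) as JSON."""
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_result(path) -> dict:
    return json.loads(Path(path).read_text())
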