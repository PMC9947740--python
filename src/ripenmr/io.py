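"""Plain-text file formats.

Echo trains, relaxation maps and ripening series travel as small text
files: one JSON header line (acquisition metadata with explicit units)
followed by a delimited numeric table.  Everything is converted to SI on
read; the header round-trips bit-exactly and values to full float
precision.

Echo-train layout::

    {"format": "ripenmr-echotrain", "kind": "cpmg", "tau": 100.0,
     "units": {"tau": "us", ...}, ...}
    # indirect	echo	amplitude
    0.0	1	0.98765
    ...

Map layout: a JSON header with the grid definition and regularization
metadata, then one CSV row per grid node (axis values in SI, weight).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParseError
from .ilt import LogGrid, RegParams, RelaxationMap
from .models import AcquisitionScheme, EchoTrain

_UNIT_FACTORS = {
    "s": 1.0, "ms": 1e-3, "us": 1e-6,
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "arb": 1.0, "dimensionless": 1.0,
}

#: Units used when writing (human-friendly; SI internally).
_WRITE_UNITS = {"tau": "us", "t1_list": "ms", "delta_list": "ms",
                "big_delta": "ms", "repetition_time": "s", "depth": "mm",
                "amplitude": "arb"}

ECHOTRAIN_FORMAT = "ripenmr-echotrain"
MAP_FORMAT = "ripenmr-map"


def _to_si(value, unit: str, field: str):
    if unit not in _UNIT_FACTORS:
        raise ParseError(f"field {field!r}: unknown unit {unit!r}")
    factor = _UNIT_FACTORS[unit]
    if isinstance(value, (list, tuple)):
        return tuple(float(v) * factor for v in value)
    return float(value) * factor


def _from_si(value, unit: str):
    factor = _UNIT_FACTORS[unit]
    if isinstance(value, (list, tuple, np.ndarray)):
        return [float(v) / factor for v in value]
    return float(value) / factor


def write_dataset(train: EchoTrain, path: Union[str, Path]) -> Path:
    """Write one echo train (JSON header line + TSV body)."""
    path = Path(path)
    s = train.scheme
    header = {
        "format": ECHOTRAIN_FORMAT,
        "version": 1,
        "kind": s.kind,
        "tau": _from_si(s.tau, _WRITE_UNITS["tau"]),
        "n_echoes": s.n_echoes,
        "t1_list": _from_si(s.t1_list, "ms") if s.t1_list else None,
        "delta_list": _from_si(s.delta_list, "ms") if s.delta_list else None,
        "big_delta": _from_si(s.big_delta, "ms") if s.big_delta else None,
        "n_scans": s.n_scans,
        "repetition_time": s.repetition_time,
        "depth": _from_si(s.depth, "mm"),
        "noise_sigma": train.noise_sigma,
        "meta": {k: v for k, v in train.meta.items()},
        "units": dict(_WRITE_UNITS),
    }
    values = np.atleast_2d(train.values)
    indirect = s.indirect_values
    if indirect is None:
        ind_col = np.zeros(1)
    else:
        ind_col = _from_si(indirect, "ms")
    lines = [json.dumps(header)]
    lines.append("# indirect\techo\tamplitude")
    for i, row in enumerate(values):
        for k, amp in enumerate(row, start=1):
            lines.append(f"{float(ind_col[i]):.9g}\t{k}\t{float(amp)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _require(header: dict, key: str):
    if key not in header:
        raise ParseError(f"missing header field {key!r}")
    return header[key]


def read_dataset(path: Union[str, Path]) -> EchoTrain:
    """Read an echo train written by :func:`write_dataset` (SI units)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ParseError(f"header is not valid JSON: {exc}") from exc
    if header.get("format") != ECHOTRAIN_FORMAT:
        raise ParseError("field 'format': not a ripenmr echo-train file")
    units = _require(header, "units")
    for field in ("kind", "tau", "n_echoes"):
        _require(header, field)
    kind = header["kind"]
    if "tau" not in units:
        raise ParseError("field 'tau': no unit declared")

    def si(field, unit_key=None):
        value = header.get(field)
        if value is None:
            return None
        unit = units.get(unit_key or field)
        if unit is None:
            raise ParseError(f"field {field!r}: no unit declared")
        return _to_si(value, unit, field)

    scheme = AcquisitionScheme(
        kind=kind,
        tau=si("tau"),
        n_echoes=int(header["n_echoes"]),
        t1_list=si("t1_list"),
        delta_list=si("delta_list"),
        big_delta=si("big_delta"),
        n_scans=int(header.get("n_scans", 1)),
        repetition_time=float(header.get("repetition_time", 0.0) or 0.0),
        depth=si("depth") if header.get("depth") is not None else 0.0,
    )
    body = [ln for ln in lines[1:] if ln and not ln.startswith("#")]
    expected = int(np.prod(scheme.shape))
    if len(body) != expected:
        raise ParseError(
            f"field 'body': {len(body)} rows, expected {expected}")
    amps = np.array([float(ln.split("\t")[2]) for ln in body])
    values = amps.reshape(scheme.shape)
    return EchoTrain(scheme=scheme, values=values,
                     noise_sigma=float(header.get("noise_sigma", 0.0)),
                     meta=dict(header.get("meta", {})))


def write_map(rmap: RelaxationMap, path: Union[str, Path]) -> Path:
    """Write a relaxation map (JSON header line + CSV body, SI units)."""
    path = Path(path)
    g = rmap.grid
    header = {
        "format": MAP_FORMAT,
        "version": 1,
        "axis_names": list(g.axis_names),
        "lower": list(g.lower),
        "upper": list(g.upper),
        "n_points": list(g.n_points),
        "lam": rmap.regularization.lam,
        "strategy": rmap.regularization.strategy,
        "residual_norm": rmap.residual_norm,
        "flags": {k: v for k, v in rmap.flags.items()
                  if k != "objective_history"},
        "units": {"T1": "s", "T2": "s", "D": "m2/s"},
    }
    axes = g.axes()
    lines = [json.dumps(header),
             "# " + ",".join(g.axis_names) + ",weight"]
    if g.ndim == 1:
        for x, w in zip(axes[0], rmap.weights):
            lines.append(f"{float(x)!r},{float(w)!r}")
    else:
        for i, a in enumerate(axes[0]):
            for j, b in enumerate(axes[1]):
                lines.append(f"{float(a)!r},{float(b)!r},{float(rmap.weights[i, j])!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_map(path: Union[str, Path]) -> RelaxationMap:
    """Read a relaxation map written by :func:`write_map`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ParseError(f"header is not valid JSON: {exc}") from exc
    if header.get("format") != MAP_FORMAT:
        raise ParseError("field 'format': not a ripenmr map file")
    grid = LogGrid(tuple(_require(header, "axis_names")),
                   tuple(_require(header, "lower")),
                   tuple(_require(header, "upper")),
                   tuple(_require(header, "n_points")))
    body = [ln for ln in lines[1:] if ln and not ln.startswith("#")]
    expected = int(np.prod(grid.shape))
    if len(body) != expected:
        raise ParseError(
            f"field 'body': {len(body)} rows, expected {expected}")
    weights = np.array([float(ln.split(",")[-1]) for ln in body])
    reg = RegParams(lam=float(_require(header, "lam")),
                    strategy=header.get("strategy", "fixed"))
    return RelaxationMap(grid=grid, weights=weights.reshape(grid.shape),
                         residual_norm=float(header.get("residual_norm", 0.0)),
                         regularization=reg,
                         flags=dict(header.get("flags", {})))


def write_series(series, path: Union[str, Path]) -> Path:
    """Ripening series as CSV (day, depth_mm, intensity, snr)."""
    from .profile import RipeningSeries  # local import avoids a cycle
    assert isinstance(series, RipeningSeries)
    path = Path(path)
    out = series.entries.copy()
    out["depth_mm"] = out.pop("depth") * 1e3
    out["sample"] = series.sample_id
    out[["sample", "day", "depth_mm", "intensity", "snr"]].to_csv(
        path, index=False)
    return path


def read_series(path: Union[str, Path]):
    from .profile import RipeningSeries
    df = pd.read_csv(path)
    for col in ("day", "depth_mm", "intensity", "snr"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}")
    entries = df.rename(columns={"depth_mm": "depth"})
    entries["depth"] = entries["depth"] * 1e-3
    sample = str(df["sample"].iloc[0]) if "sample" in df.columns else ""
    return RipeningSeries(entries[["day", "depth", "intensity", "snr"]],
                          sample_id=sample)
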