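"""Depth-resolved ripening metrics.

The single scalar tracked through ripening is the fifth-echo CPMG
amplitude (total echo time 1 ms at the default 200-us echo spacing): it
is late enough to exclude rigid macromolecular protons and early enough
to capture every mobile pool.  From it derive:

* an SNR estimate (fifth echo over the noise floor of the echo tail);
* the drying time of a depth — the first ripening day whose SNR falls
  below 30 and stays below it;
* normalized (max = 100) intensity series and first-to-last percent
  decreases summarising how much a layer dried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidSchemeError, RangeError
from .models import EchoTrain

SNR_DRYING_THRESHOLD = 30.0


@dataclass
class RipeningSeries:
    """(day, depth) -> (fifth-echo intensity, SNR) records for one sample."""

    entries: pd.DataFrame          # columns: day, depth, intensity, snr
    sample_id: str = ""
    weight_series: Optional[pd.DataFrame] = None   # columns: day, mass

    def __post_init__(self):
        required = {"day", "depth", "intensity", "snr"}
        missing = required - set(self.entries.columns)
        if missing:
            raise DegenerateInputError(f"entries missing columns {missing}")
        if self.entries.duplicated(["day", "depth"]).any():
            raise DegenerateInputError("duplicate (day, depth) entry")
        if (self.entries["intensity"] < 0).any():
            raise DegenerateInputError("negative intensity entry")

    def at_depth(self, depth: float) -> pd.DataFrame:
        sel = self.entries[np.isclose(self.entries["depth"], depth)]
        if sel.empty:
            raise RangeError(f"depth {depth} not covered by series")
        return sel.sort_values("day")


def signal_intensity(train: EchoTrain) -> float:
    """Fifth-echo amplitude of a CPMG train (t = 10 tau, i.e. 1 ms at the
    default echo spacing)."""
    if train.scheme.kind != "cpmg":
        raise InvalidSchemeError("signal_intensity expects a CPMG train")
    if train.scheme.n_echoes < 5:
        raise InvalidSchemeError("need >= 5 echoes")
    return float(train.values[4])


def snr(train: EchoTrain) -> float:
    """Fifth-echo amplitude over the noise floor of the echo tail.

    The noise floor is the standard deviation of the last 10% of echoes
    after removing their mean.  A zero-variance tail with nonzero signal
    returns ``inf``; an all-zero degenerate train raises.
    """
    if train.scheme.kind != "cpmg":
        raise InvalidSchemeError("snr expects a CPMG train")
    n = train.scheme.n_echoes
    if n < 64:
        raise InvalidSchemeError("need >= 64 echoes for a noise-floor tail")
    tail = train.values[-max(1, n // 10):]
    floor = float(np.std(tail - tail.mean()))
    signal = float(train.values[4])
    if floor == 0.0:
        if signal == 0.0:
            raise DegenerateInputError("constant tail and zero signal")
        return math.inf
    return signal / floor


def series_from_trains(trains: Iterable[EchoTrain],
                       sample_id: str = "") -> RipeningSeries:
    """Build a ripening series from CPMG trains tagged with day/depth."""
    rows = []
    for t in trains:
        if t.scheme.kind != "cpmg":
            continue
        rows.append({"day": int(t.meta["day"]),
                     "depth": float(t.meta.get("depth", t.scheme.depth)),
                     "intensity": max(0.0, signal_intensity(t)),
                     "snr": snr(t)})
    if not rows:
        raise DegenerateInputError("no CPMG trains supplied")
    return RipeningSeries(pd.DataFrame(rows), sample_id=sample_id)


def drying_time(series: RipeningSeries, depth: float,
                threshold: float = SNR_DRYING_THRESHOLD) -> Optional[int]:
    """First day with SNR below threshold and no later recovery.

    Returns ``None`` when the depth never (persistently) crosses the
    threshold.  The persistence rule ignores single-day noise dips.
    """
    sel = series.at_depth(depth)
    below = (sel["snr"] < threshold).to_numpy()
    days = sel["day"].to_numpy()
    # last False position: everything after it is persistently below
    above_idx = np.flatnonzero(~below)
    start = 0 if above_idx.size == 0 else above_idx[-1] + 1
    if start >= len(days):
        return None
    return int(days[start])


def normalize_to_100(values) -> np.ndarray:
    """Scale a series so its maximum is exactly 100."""
    v = np.asarray(values, dtype=float)
    top = v.max() if v.size else 0.0
    if top <= 0:
        raise DegenerateInputError("series has no positive value")
    return (v / top) * 100.0


def percent_decrease(series: RipeningSeries, depth: float) -> float:
    """100 x (first - last) / first of the fifth-echo intensity at a depth."""
    sel = series.at_depth(depth)
    if len(sel) < 2:
        raise DegenerateInputError("need >= 2 days at the depth")
    first = float(sel["intensity"].iloc[0])
    last = float(sel["intensity"].iloc[-1])
    if first == 0.0:
        raise DegenerateInputError("first-day intensity is zero")
    return 100.0 * (first - last) / first
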