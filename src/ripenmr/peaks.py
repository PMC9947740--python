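"""Peak detection, Gaussian fitting and classification on relaxation maps.

Peaks are located as local maxima of the inverted distribution, then each
is fitted with an axis-aligned Gaussian *in log10 coordinates* (relaxation
peaks are near-symmetric on a log axis).  The fitted centre is the peak
position; the analytic integral of the Gaussian is the peak area used for
ripening trajectories.

Class labels follow the component assignment of a three-pool cheese:

* T1-T2 maps — ``artifact`` when the fitted T2 exceeds T1 (unphysical,
  inversion noise), ``P`` (casein-trapped water) when T1:T2 >= 10,
  otherwise ``W`` (gel water, T2 <= 65 ms) or ``F`` (liquid fat).
* D-T2 maps — ``WP`` (aqueous pool, D >= 3e-10 m^2/s), ``F1``
  (3e-11 <= D < 3e-10) and ``F2`` (D < 3e-11): fat pools of two distinct
  globule sizes.

All thresholds are configurable via :class:`ClassThresholds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import FitError
from .ilt import RelaxationMap

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ClassThresholds:
    """Decision boundaries for component labelling (SI units)."""

    p_ratio: float = 10.0        # T1:T2 at or above which a peak is P
    w_t2_max: float = 65e-3      # T2 below which a non-P peak is W
    d_wp_min: float = 3e-10      # D above which a D-T2 peak is aqueous
    d_f1_min: float = 3e-11      # D range floor of the F1 fat pool


DEFAULT_THRESHOLDS = ClassThresholds()


@dataclass
class PeakFit:
    """One fitted Gaussian peak.

    ``center`` and ``widths`` are per-axis values in log10 of SI units;
    ``area`` is the analytic integral of the Gaussian in those
    coordinates.
    """

    axis_names: Tuple[str, ...]
    center: Tuple[float, ...]
    widths: Tuple[float, ...]
    amplitude: float
    area: float
    label: str = "unassigned"
    quality: float = math.inf

    @property
    def center_si(self) -> Tuple[float, ...]:
        return tuple(10.0 ** c for c in self.center)

    @property
    def converged(self) -> bool:
        return math.isfinite(self.quality)


def detect_peaks(rmap: RelaxationMap, min_rel_height: float = 0.02
                 ) -> List[Tuple[int, ...]]:
    """Local maxima above ``min_rel_height`` x global maximum.

    Uses a 2-neighbourhood in 1D and an 8-neighbourhood in 2D; returns
    index tuples sorted by height, highest first.  A null map yields an
    empty list.
    """
    w = rmap.weights
    top = w.max() if w.size else 0.0
    if top <= 0.0:
        return []
    floor = min_rel_height * top
    if w.ndim == 1:
        left = np.r_[-np.inf, w[:-1]]
        right = np.r_[w[1:], -np.inf]
        is_max = (w >= left) & (w >= right)
    else:
        is_max = ndimage.maximum_filter(w, size=3, mode="constant") == w
    is_max &= w >= floor
    seeds = [tuple(idx) for idx in np.argwhere(is_max)]
    seeds.sort(key=lambda idx: -w[idx])
    # collapse plateau duplicates: keep a seed only if no kept neighbour
    kept: List[Tuple[int, ...]] = []
    for s in seeds:
        if all(max(abs(a - b) for a, b in zip(s, k)) > 1 for k in kept):
            kept.append(s)
    return kept


def _gauss_nd(x_list, amp, centers, sigmas):
    out = amp
    for x, mu, sg in zip(x_list, centers, sigmas):
        out = out * np.exp(-0.5 * ((x - mu) / sg) ** 2)
    return out


def fit_gaussian(rmap: RelaxationMap, seed: Tuple[int, ...],
                 window: int = 5,
                 competitors: Sequence[Tuple[int, ...]] = ()) -> PeakFit:
    """Least-squares fit of an axis-aligned log10-Gaussian around a seed.

    The fitted area is analytic: ``sqrt(2 pi) * A * sigma`` in 1D and
    ``2 pi * A * sigma_x * sigma_y`` in 2D.  Grid nodes strictly closer
    (in grid steps) to one of the ``competitors`` than to the seed are
    excluded, so a neighbouring peak's shoulder cannot drag the fit.
    Non-convergence returns a flagged fit with infinite ``quality``
    instead of raising.
    """
    if window < 3:
        raise FitError("window must span >= 3 grid steps per axis")
    axes_log = [np.log10(a) for a in rmap.grid.axes()]
    ndim = rmap.grid.ndim
    seed = tuple(int(s) for s in seed)
    slices = []
    for d, i in enumerate(seed):
        n = rmap.grid.shape[d]
        if not (0 <= i < n):
            raise FitError(f"seed index {i} outside axis {d}")
        slices.append(slice(max(0, i - window), min(n, i + window + 1)))
    sub = rmap.weights[tuple(slices)]
    n_params = 1 + 2 * ndim
    if sub.size < n_params:
        raise FitError("window holds fewer points than fit parameters")

    sub_axes = [ax[s] for ax, s in zip(axes_log, slices)]
    mesh = np.meshgrid(*sub_axes, indexing="ij")
    steps = [ax[1] - ax[0] for ax in axes_log]
    amp0 = float(rmap.weights[seed])
    c0 = [ax_log[i] for ax_log, i in zip(axes_log, seed)]

    keep = np.ones(sub.shape, dtype=bool)
    others = [c for c in competitors if tuple(c) != seed]
    if others:
        grids_idx = np.meshgrid(*[np.arange(s.start, s.stop)
                                  for s in slices], indexing="ij")
        d_seed = sum((g - i) ** 2 for g, i in zip(grids_idx, seed))
        for comp in others:
            d_comp = sum((g - i) ** 2 for g, i in zip(grids_idx, comp))
            keep &= d_seed <= d_comp
        if keep.sum() < n_params:
            keep = np.ones(sub.shape, dtype=bool)
    keep_flat = keep.ravel()

    def resid(theta):
        amp = theta[0]
        centers = theta[1:1 + ndim]
        sigmas = theta[1 + ndim:]
        return ((_gauss_nd(mesh, amp, centers, sigmas) - sub)
                .ravel()[keep_flat])

    lo = [1e-12 * max(amp0, 1e-300)]
    hi = [np.inf]
    x0 = [max(amp0, 1e-300)]
    for d in range(ndim):
        span = sub_axes[d][-1] - sub_axes[d][0] + steps[d]
        lo += [sub_axes[d][0] - steps[d]]
        hi += [sub_axes[d][-1] + steps[d]]
        x0 += [c0[d]]
        # sigma bounds appended after centers
    for d in range(ndim):
        span = sub_axes[d][-1] - sub_axes[d][0] + steps[d]
        lo += [0.2 * steps[d]]
        hi += [2.0 * span]
        x0 += [max(steps[d], 0.2 * steps[d] * 1.001)]
    try:
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
    except Exception:
        return PeakFit(rmap.grid.axis_names, tuple(c0), tuple(steps),
                       amp0, 0.0, quality=math.inf)
    amp = float(sol.x[0])
    centers = tuple(float(v) for v in sol.x[1:1 + ndim])
    sigmas = tuple(float(v) for v in sol.x[1 + ndim:])
    if ndim == 1:
        area = SQRT_2PI * amp * sigmas[0]
    else:
        area = 2.0 * math.pi * amp * sigmas[0] * sigmas[1]
    quality = float(np.linalg.norm(sol.fun)) if sol.success else math.inf
    return PeakFit(rmap.grid.axis_names, centers, sigmas, amp, area,
                   quality=quality)


def classify_peak(fit: PeakFit, map_kind: str,
                  thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    """Label one fitted peak according to the map kind."""
    si = fit.center_si
    if map_kind == "t1t2":
        t1, t2 = si
        if t2 > t1:
            return "artifact"
        if t1 / t2 >= thresholds.p_ratio:
            return "P"
        return "W" if t2 <= thresholds.w_t2_max else "F"
    if map_kind == "dt2":
        d, _t2 = si
        if d >= thresholds.d_wp_min:
            return "WP"
        return "F1" if d >= thresholds.d_f1_min else "F2"
    return "unassigned"


def fit_peaks(rmap: RelaxationMap, min_rel_height: float = 0.02,
              window: int = 5,
              thresholds: ClassThresholds = DEFAULT_THRESHOLDS
              ) -> List[PeakFit]:
    """Detect, fit and classify every peak of one map."""
    fits = []
    seeds = detect_peaks(rmap, min_rel_height)
    for seed in seeds:
        fit = fit_gaussian(rmap, seed, window=window, competitors=seeds)
        fits.append(replace(fit, label=classify_peak(fit, rmap.kind,
                                                     thresholds)))
    return fits


def _log_distance(a: Sequence[float], b: Sequence[float]) -> float:
    return math.dist(a, b)


def peak_table(maps_by_day: Sequence[Tuple[int, RelaxationMap]],
               min_rel_height: float = 0.02, window: int = 5,
               thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
               normalize_day1: bool = False) -> pd.DataFrame:
    """Per-day trajectory table of peak centres and areas.

    Peaks are matched across days by label first, then by nearest log
    distance to the label's previous centre (ties toward larger area).
    With ``normalize_day1`` the areas are scaled so the first day's total
    (non-artifact) area is 1.  A label absent on a day is simply absent
    from the table.
    """
    if len(maps_by_day) == 0:
        raise FitError("peak_table needs >= 1 map")
    rows = []
    last_center = {}
    for day, rmap in maps_by_day:
        fits = fit_peaks(rmap, min_rel_height, window, thresholds)
        by_label = {}
        for f in fits:
            by_label.setdefault(f.label, []).append(f)
        for label, group in by_label.items():
            if label == "artifact":
                continue
            if label in last_center and len(group) > 1:
                ref = last_center[label]
                group.sort(key=lambda f: (_log_distance(f.center, ref),
                                          -f.area))
            else:
                group.sort(key=lambda f: -f.area)
            best = group[0]
            last_center[label] = best.center
            row = {"day": day, "label": label, "area": best.area,
                   "amplitude": best.amplitude, "quality": best.quality}
            for name, c, w in zip(best.axis_names, best.center_si,
                                  best.widths):
                row[f"center_{name}"] = c
                row[f"width_{name}"] = w
            rows.append(row)
    table = pd.DataFrame(rows)
    if normalize_day1 and len(table):
        day1 = table["day"].min()
        total = table.loc[table["day"] == day1, "area"].sum()
        if total > 0:
            table["area"] = table["area"] / total
    return table
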