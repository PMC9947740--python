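"""Synthetic multi-depth, multi-day echo-train generator.

The generator emulates the statistical structure of a 20-day ripening run
of a soft surface-mold cheese probed with a single-sided sensor at depths
of 2-5 mm:

* a three-pool proton mixture — gel-network water (W), casein-trapped
  water (P), and liquid fat (F) split over two globule-size diffusion
  pools (F1, F2);
* day-1 pool positions at the observed (gradient-weighted) values:
  W at (T1, T2) = (320, 60) ms, P at (160, 2.4) ms, F at (100, 70) ms,
  with D ~ 1e-9 m^2/s for the aqueous pools and 1e-10 / 1e-11 m^2/s for
  the two fat pools;
* monotone drying: the total amplitude in the soft centre (5 mm) falls by
  ~30% (sample "1") or ~13% (sample "2") over 20 days, relaxation times
  drift downward, and the skin layers lose their signal entirely at a
  depth-dependent drying day (2 mm dries on day 8);
* additive zero-mean Gaussian noise on every sampled point.

Because the stored T2 values are the observed, diffusion-weighted ones,
simulation uses ``forward_signal`` with gradient weighting off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from . import models
from .errors import DegenerateInputError, InvalidSchemeError, RangeError
from .models import (AcquisitionScheme, ComponentMixture, EchoTrain,
                     InstrumentSpec, RelaxationComponent)

#: Default seed for reproducible documentation runs.
DEFAULT_SEED = 7197359

#: Sensing depths, m (2, 2.5, 3, 4, 5 mm).
DEFAULT_DEPTHS = (2e-3, 2.5e-3, 3e-3, 4e-3, 5e-3)

#: Day-1 amplitude of each depth relative to the soft centre.  The
#: outermost layer starts 36% below the centre.
_DEPTH_AMPLITUDE = {2e-3: 0.64, 2.5e-3: 0.75, 3e-3: 0.85, 4e-3: 0.95, 5e-3: 1.0}

#: Day on which the signal of a (drying) depth reaches zero.
DEFAULT_DRYING_DAYS = {2e-3: 8, 2.5e-3: 12, 3e-3: 16}

#: Fractional loss of total amplitude at 5 mm between day 1 and day 20.
_SAMPLE_DECLINE = {"1": 0.30, "2": 0.13}

_LAST_DAY = 20


def default_scheme(kind: str, depth: float = 5e-3,
                   n_echoes: int = 512) -> AcquisitionScheme:
    """Acquisition defaults: 2*tau = 200 us, 512 echoes; 32 log-spaced t1
    in 1-2500 ms; 32 log-spaced delta in 0.1-5 ms with Delta = 5 ms."""
    if kind == "cpmg":
        return AcquisitionScheme("cpmg", tau=100e-6, n_echoes=n_echoes,
                                 n_scans=128, depth=depth)
    if kind == "satrec_cpmg":
        t1 = np.logspace(math.log10(1e-3), math.log10(2.5), 32)
        return AcquisitionScheme("satrec_cpmg", tau=100e-6, n_echoes=n_echoes,
                                 t1_list=tuple(t1), n_scans=32, depth=depth)
    if kind == "ste_cpmg":
        delta = np.logspace(math.log10(0.1e-3), math.log10(5e-3), 32)
        return AcquisitionScheme("ste_cpmg", tau=100e-6, n_echoes=n_echoes,
                                 delta_list=tuple(delta), big_delta=5e-3,
                                 n_scans=32, depth=depth)
    raise InvalidSchemeError(f"unknown scheme kind {kind!r}")


def _ripening_fraction(day: int) -> float:
    """Log-linear progress coordinate: 0 at day 1, 1 at day 20."""
    return math.log(day) / math.log(_LAST_DAY)


def day1_t2_mixture() -> ComponentMixture:
    """Three-pool mixture at the observed 1D T2 positions.

    T2 = 10, 30 and 100 ms with the middle (gel-water) pool dominant;
    amplitudes 0.2 / 0.6 / 0.2.
    """
    return ComponentMixture(
        [RelaxationComponent(0.2, T1=160e-3, T2=10e-3),
         RelaxationComponent(0.6, T1=320e-3, T2=30e-3),
         RelaxationComponent(0.2, T1=100e-3, T2=100e-3)],
        labels=["P", "W", "F"],
    )


def default_component_table(day: int, depth: float,
                            sample: str = "1") -> ComponentMixture:
    """Per-day, per-depth ground-truth mixture of the default scenario.

    Trajectories are log-linear in day between the day-1 anchors and the
    day-20 endpoints; depths that dry out decline linearly to zero
    amplitude at their drying day.
    """
    if not (1 <= day <= _LAST_DAY):
        raise RangeError(f"day {day} outside 1..{_LAST_DAY}")
    if depth not in _DEPTH_AMPLITUDE:
        raise RangeError(f"depth {depth} not in default depth set")
    if sample not in _SAMPLE_DECLINE:
        raise RangeError(f"unknown sample {sample!r}")

    f = _ripening_fraction(day)
    total = _DEPTH_AMPLITUDE[depth] * (1.0 - _SAMPLE_DECLINE[sample] * f)
    dry_day = DEFAULT_DRYING_DAYS.get(depth)
    if dry_day is not None:
        total *= max(0.0, (dry_day - day) / (dry_day - 1.0))

    # Water share shrinks by 20% over the run; protein and fat pick up the
    # slack in a 1:2 ratio, so their relative integrals grow.
    w = 0.7 * (1.0 - 0.20 * f)
    p = 0.1 + (0.7 - w) / 3.0
    fat = 0.2 + 2.0 * (0.7 - w) / 3.0

    relax = 1.0 - 0.30 * f          # downward drift of T1, T2
    d_wp = 1e-9 * (1.0 - 0.30 * f)  # aqueous D falls as the gel shrinks

    if total <= 0.0:
        # Dried-out layer: amplitudes zero; keep a unit placeholder shape
        # by returning an all-but-zero mixture (simulate() emits pure noise).
        total = 0.0
    comps = [
        RelaxationComponent(total * w, T1=320e-3 * relax, T2=60e-3 * relax, D=d_wp),
        RelaxationComponent(total * p, T1=160e-3 * relax, T2=2.4e-3 * relax, D=d_wp),
        RelaxationComponent(total * fat / 2, T1=100e-3 * relax, T2=70e-3 * relax, D=1e-10),
        RelaxationComponent(total * fat / 2, T1=100e-3 * relax, T2=70e-3 * relax, D=1e-11),
    ]
    labels = ["W", "P", "F1", "F2"]
    if total == 0.0:
        return _ZeroMixture(comps, labels)
    return ComponentMixture(comps, labels)


class _ZeroMixture(ComponentMixture):
    """Mixture of a dried-out layer: all amplitudes zero (noise only)."""

    def __post_init__(self):
        if len(self.components) == 0:
            raise DegenerateInputError("mixture must contain >= 1 component")
        if self.labels is None:
            self.labels = ["unassigned"] * len(self.components)


@dataclass
class RipeningScenario:
    """Study conditions for one synthetic ripening run."""

    days: Sequence[int] = tuple(range(1, _LAST_DAY + 1))
    depths: Sequence[float] = DEFAULT_DEPTHS
    component_table: Callable[[int, float], ComponentMixture] = None
    drying_day_by_depth: Optional[Dict[float, int]] = None
    noise_sigma: float = 0.0
    seed: int = DEFAULT_SEED
    sample: str = "1"

    def __post_init__(self):
        days = tuple(int(d) for d in self.days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise RangeError("days must be strictly increasing")
        self.days = days
        if self.noise_sigma < 0:
            raise DegenerateInputError("noise_sigma must be >= 0")
        if self.component_table is None:
            sample = self.sample
            self.component_table = (
                lambda day, depth: default_component_table(day, depth, sample))
        if self.drying_day_by_depth is None:
            self.drying_day_by_depth = {
                d: dd for d, dd in DEFAULT_DRYING_DAYS.items()
                if d in self.depths}

    @classmethod
    def default(cls, sample: str = "1", target_snr: float = 500.0,
                seed: int = DEFAULT_SEED) -> "RipeningScenario":
        """Scenario with noise calibrated to a day-1 centre SNR target."""
        sigma = noise_sigma_for_snr(
            target_snr, default_component_table(1, 5e-3, sample),
            default_scheme("cpmg"))
        return cls(noise_sigma=sigma, seed=seed, sample=sample)


def _reference_slice(train: EchoTrain) -> np.ndarray:
    """CPMG slice used for SNR bookkeeping: the fully recovered / least
    diffusion-weighted row of a 2D train, or the train itself."""
    if train.values.ndim == 1:
        return train.values
    if train.scheme.kind == "satrec_cpmg":
        return train.values[-1]      # longest recovery time
    return train.values[0]           # shortest delta


def noise_sigma_for_snr(target_snr: float, mixture: ComponentMixture,
                        scheme: AcquisitionScheme,
                        inst: InstrumentSpec = InstrumentSpec()) -> float:
    """Noise level sigma whose fifth-echo SNR equals ``target_snr`` in
    expectation (SNR as estimated by :func:`ripenmr.profile.snr`)."""
    if target_snr <= 0:
        raise DegenerateInputError("target_snr must be positive")
    if mixture.total_amplitude <= 0:
        raise DegenerateInputError("zero-amplitude mixture")
    clean = models.forward_signal(mixture, scheme, inst)
    ref = _reference_slice(clean)
    if len(ref) < 5 or ref[4] <= 0:
        raise DegenerateInputError("reference slice carries no fifth echo")
    return float(ref[4]) / float(target_snr)


def simulate(scenario: RipeningScenario, scheme_kind: str,
             inst: InstrumentSpec = InstrumentSpec(),
             n_echoes: int = 512) -> List[EchoTrain]:
    """Simulate the scenario under one acquisition scheme kind.

    Deterministic given ``scenario.seed``; trains are emitted day-major,
    depth-minor.  A depth past its drying day yields pure noise.
    """
    if scheme_kind not in models.SCHEME_KINDS:
        raise InvalidSchemeError(f"unknown scheme kind {scheme_kind!r}")
    rng = np.random.default_rng(scenario.seed)
    trains: List[EchoTrain] = []
    for day in scenario.days:
        for depth in scenario.depths:
            scheme = default_scheme(scheme_kind, depth=depth, n_echoes=n_echoes)
            mixture = scenario.component_table(day, depth)
            dry_day = scenario.drying_day_by_depth.get(depth)
            dried = dry_day is not None and day >= dry_day
            if dried or mixture.total_amplitude <= 0:
                clean = np.zeros(scheme.shape)
            else:
                clean = models.forward_signal(mixture, scheme, inst).values
            noisy = clean + rng.normal(0.0, scenario.noise_sigma, scheme.shape) \
                if scenario.noise_sigma > 0 else clean
            trains.append(EchoTrain(
                scheme=scheme, values=noisy, noise_sigma=scenario.noise_sigma,
                meta={"day": day, "depth": depth, "sample": scenario.sample,
                      "dried": bool(dried)}))
    return trains
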