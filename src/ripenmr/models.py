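"""Physical forward models for single-sided (constant-gradient) NMR relaxometry.

The measurements this package deals with are echo trains acquired with a
unilateral NMR sensor whose permanent field gradient is strong (several
T/m).  Three acquisition schemes are modelled:

``cpmg``
    A plain CPMG multi-echo train; the signal decays multiexponentially
    with the transverse relaxation times T2 of the contributing pools,

    .. math:: S(t) = \\sum_i a_i\\, e^{-t/T_{2,i}},  \\qquad t_k = 2\\tau k .

``satrec_cpmg``
    A saturation-recovery block (magnetization nulled, then allowed to
    recover for a time t1) followed by CPMG detection; encodes T1 against
    T2 through the factor :math:`1 - e^{-t_1/T_1}`.

``ste_cpmg``
    A stimulated-echo block followed by CPMG detection.  In a constant
    gradient g the stimulated echo is diffusion-attenuated with the
    Stejskal-Tanner-form exponent
    :math:`\\gamma^2 g^2 \\delta^2 D (\\Delta - \\delta/3)`,
    encoding the self-diffusion coefficient D against T2.

Because the gradient is always on, diffusion also shortens the T2 observed
under CPMG ("apparent T2"):

.. math:: 1/T_{2,\\mathrm{app}} = 1/T_2 + \\gamma^2\\tau^2 g^2 D / 3 .

All quantities are strict SI internally (seconds, metres, tesla); display
layers convert to ms / um / decades of m^2 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError, GridError, InvalidSchemeError

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
GAMMA_1H = 2.6752218744e8

#: Sentinel accepted by :func:`apparent_t2` for an infinitely long true T2.
T2_INFINITE = math.inf

SCHEME_KINDS = ("cpmg", "satrec_cpmg", "ste_cpmg")


@dataclass(frozen=True)
class InstrumentSpec:
    """Static constants of the single-sided sensor.

    Defaults are a 13.29 MHz unilateral magnet with a 7.28 T/m static
    gradient, probed with protons.
    """

    gamma: float = GAMMA_1H          # rad s^-1 T^-1
    gradient_g: float = 7.28         # T m^-1
    frequency: float = 13.29e6       # Hz

    def __post_init__(self):
        if self.gamma <= 0:
            raise DomainError("gamma must be positive")
        if self.gradient_g < 0:
            raise DomainError("gradient_g must be non-negative")


@dataclass(frozen=True)
class AcquisitionScheme:
    """Parameters of one experiment.

    Parameters
    ----------
    kind : {"cpmg", "satrec_cpmg", "ste_cpmg"}
    tau : float
        Half echo time in seconds (echo spacing is ``2 * tau``).
    n_echoes : int
        Number of recorded echoes.
    t1_list : sequence of float, optional
        Saturation-recovery times in seconds (``satrec_cpmg`` only),
        strictly increasing.
    delta_list : sequence of float, optional
        Stimulated-echo 90-90 pulse gaps delta, seconds (``ste_cpmg`` only).
    big_delta : float, optional
        Diffusion encoding time Delta, seconds (``ste_cpmg`` only).
    n_scans, repetition_time, depth :
        Bookkeeping metadata (scan count, recycle delay in s, sensing
        depth in m); not used by the kernels.
    """

    kind: str
    tau: float = 100e-6
    n_echoes: int = 512
    t1_list: Optional[tuple] = None
    delta_list: Optional[tuple] = None
    big_delta: Optional[float] = None
    n_scans: int = 1
    repetition_time: float = 2.5
    depth: float = 5e-3

    def __post_init__(self):
        if self.kind not in SCHEME_KINDS:
            raise InvalidSchemeError(f"unknown scheme kind {self.kind!r}")
        if not (self.tau > 0):
            raise InvalidSchemeError("tau must be positive")
        if self.n_echoes < 1:
            raise InvalidSchemeError("n_echoes must be >= 1")
        if self.kind == "satrec_cpmg":
            if self.t1_list is None or len(self.t1_list) == 0:
                raise InvalidSchemeError("satrec_cpmg requires t1_list")
            t1 = np.asarray(self.t1_list, dtype=float)
            object.__setattr__(self, "t1_list", tuple(t1))
            if np.any(t1 <= 0) or np.any(np.diff(t1) <= 0):
                raise InvalidSchemeError(
                    "t1_list must be strictly increasing and positive")
        if self.kind == "ste_cpmg":
            if self.delta_list is None or len(self.delta_list) == 0:
                raise InvalidSchemeError("ste_cpmg requires delta_list")
            if self.big_delta is None or self.big_delta <= 0:
                raise InvalidSchemeError("ste_cpmg requires big_delta > 0")
            d = np.asarray(self.delta_list, dtype=float)
            object.__setattr__(self, "delta_list", tuple(d))
            if np.any(d <= 0):
                raise InvalidSchemeError("delta values must be positive")
            if np.any(self.big_delta - d / 3.0 <= 0):
                raise InvalidSchemeError(
                    "every delta must satisfy Delta - delta/3 > 0")

    @property
    def indirect_values(self) -> Optional[np.ndarray]:
        """Indirect-dimension grid (t1 or delta) or None for plain CPMG."""
        if self.kind == "satrec_cpmg":
            return np.asarray(self.t1_list, dtype=float)
        if self.kind == "ste_cpmg":
            return np.asarray(self.delta_list, dtype=float)
        return None

    @property
    def shape(self) -> tuple:
        ind = self.indirect_values
        if ind is None:
            return (self.n_echoes,)
        return (len(ind), self.n_echoes)


@dataclass(frozen=True)
class RelaxationComponent:
    """One relaxation/diffusion pool (amplitude, T1, T2, D), SI units."""

    amplitude: float
    T1: float
    T2: float
    D: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise DomainError("amplitude must be non-negative")
        if not (self.T2 > 0):
            raise DomainError("T2 must be positive")
        if self.T1 < self.T2:
            raise DomainError("T1 must be >= T2")
        if self.D < 0:
            raise DomainError("D must be non-negative")


@dataclass
class ComponentMixture:
    """Ground-truth container: an ordered set of pools with class labels."""

    components: Sequence[RelaxationComponent]
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        if len(self.components) == 0:
            raise DegenerateInputError("mixture must contain >= 1 component")
        if self.labels is None:
            self.labels = ["unassigned"] * len(self.components)
        if len(self.labels) != len(self.components):
            raise DomainError("labels must parallel components")
        if self.total_amplitude <= 0:
            raise DegenerateInputError("mixture amplitudes must sum to > 0")

    @property
    def total_amplitude(self) -> float:
        return float(sum(c.amplitude for c in self.components))

    def scaled(self, factor: float) -> "ComponentMixture":
        return ComponentMixture(
            [RelaxationComponent(c.amplitude * factor, c.T1, c.T2, c.D)
             for c in self.components],
            list(self.labels),
        )


@dataclass
class EchoTrain:
    """A measured or simulated signal on its acquisition grid.

    ``values`` is 1D ``(n_echoes,)`` for CPMG or 2D
    ``(n_indirect, n_echoes)`` for the correlation schemes.
    """

    scheme: AcquisitionScheme
    values: np.ndarray
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.scheme.shape:
            raise InvalidSchemeError(
                f"values shape {self.values.shape} does not match scheme "
                f"shape {self.scheme.shape}")


def cpmg_times(scheme: AcquisitionScheme) -> np.ndarray:
    """Echo-centre times t_k = 2*tau*k for k = 1..n, seconds."""
    if not (scheme.tau > 0) or scheme.n_echoes < 1:
        raise InvalidSchemeError("tau must be > 0 and n_echoes >= 1")
    return 2.0 * scheme.tau * np.arange(1, scheme.n_echoes + 1)


def cpmg_kernel(times: np.ndarray, t2_grid: np.ndarray) -> np.ndarray:
    """Transverse-decay kernel K[i, j] = exp(-t_i / T2_j)."""
    times = np.asarray(times, dtype=float)
    t2 = np.asarray(t2_grid, dtype=float)
    if np.any(t2 <= 0):
        raise GridError("T2 grid values must be positive")
    if np.any(times <= 0):
        raise InvalidSchemeError("echo times must be positive")
    return np.exp(-times[:, None] / t2[None, :])


def satrec_factor(t1_times: np.ndarray, t1_grid: np.ndarray) -> np.ndarray:
    """Saturation-recovery kernel K[i, j] = 1 - exp(-t1_i / T1_j)."""
    t1_times = np.asarray(t1_times, dtype=float)
    t1 = np.asarray(t1_grid, dtype=float)
    if np.any(t1 <= 0):
        raise GridError("T1 grid values must be positive")
    if np.any(t1_times <= 0):
        raise InvalidSchemeError("recovery times must be positive")
    return 1.0 - np.exp(-t1_times[:, None] / t1[None, :])


def ste_diffusion_factor(delta, big_delta: float, D,
                         inst: InstrumentSpec = InstrumentSpec()) -> np.ndarray:
    """Stimulated-echo diffusion attenuation in a constant gradient.

    Returns ``exp(-gamma^2 g^2 delta^2 D (Delta - delta/3))``; equals 1
    when D = 0 or g = 0.  ``delta`` and ``D`` may be arrays (broadcast).
    """
    delta = np.asarray(delta, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(delta <= 0):
        raise InvalidSchemeError("delta must be positive")
    if np.any(big_delta - delta / 3.0 <= 0):
        raise InvalidSchemeError("Delta - delta/3 must be positive")
    if np.any(D < 0):
        raise DomainError("D must be non-negative")
    b = (inst.gamma ** 2) * (inst.gradient_g ** 2) * delta ** 2 * (big_delta - delta / 3.0)
    return np.exp(-b * D)


def apparent_t2(T2_true: float, tau: float, D: float,
                inst: InstrumentSpec = InstrumentSpec()) -> float:
    """Apparent T2 under CPMG in a constant gradient.

    ``1/T2app = 1/T2 + gamma^2 tau^2 g^2 D / 3``.  ``T2_true`` may be
    ``math.inf`` (free-diffusion limit: the 1/T2 term vanishes).
    """
    if T2_true <= 0:
        raise DomainError("T2_true must be positive (or inf)")
    if tau < 0 or D < 0:
        raise DomainError("tau and D must be non-negative")
    rate = (0.0 if math.isinf(T2_true) else 1.0 / T2_true)
    rate += (inst.gamma ** 2) * (tau ** 2) * (inst.gradient_g ** 2) * D / 3.0
    if rate == 0.0:
        return math.inf
    return 1.0 / rate


def rms_displacement(D: float, big_delta: float) -> float:
    """Root-mean-square displacement z = sqrt(2 * Delta * D), metres."""
    if D < 0:
        raise DomainError("D must be non-negative")
    if big_delta <= 0:
        raise DomainError("Delta must be positive")
    return math.sqrt(2.0 * big_delta * D)


def forward_signal(mixture: ComponentMixture, scheme: AcquisitionScheme,
                   inst: InstrumentSpec = InstrumentSpec(),
                   apply_gradient_weighting: bool = False) -> EchoTrain:
    """Noiseless signal of a discrete mixture under one acquisition scheme.

    With ``apply_gradient_weighting`` each component's T2 is first replaced
    by its gradient-shortened apparent value (components whose stored T2
    already is the observed, diffusion-weighted one should leave the flag
    off).
    """
    if len(mixture.components) == 0:
        raise DegenerateInputError("empty mixture")
    times = cpmg_times(scheme)
    amps = np.array([c.amplitude for c in mixture.components])
    t2s = np.array([
        apparent_t2(c.T2, scheme.tau, c.D, inst) if apply_gradient_weighting
        else c.T2
        for c in mixture.components
    ])
    decay = np.exp(-times[None, :] / t2s[:, None])        # (ncomp, nechoes)

    if scheme.kind == "cpmg":
        values = amps @ decay
    elif scheme.kind == "satrec_cpmg":
        t1s = np.array([c.T1 for c in mixture.components])
        rec = 1.0 - np.exp(-np.asarray(scheme.t1_list)[:, None] / t1s[None, :])
        values = (rec * amps[None, :]) @ decay
    elif scheme.kind == "ste_cpmg":
        ds = np.array([c.D for c in mixture.components])
        att = ste_diffusion_factor(
            np.asarray(scheme.delta_list)[:, None], scheme.big_delta,
            ds[None, :], inst)
        values = (att * amps[None, :]) @ decay
    else:  # pragma: no cover - guarded by AcquisitionScheme
        raise InvalidSchemeError(scheme.kind)

    return EchoTrain(scheme=scheme, values=values, noise_sigma=0.0)
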