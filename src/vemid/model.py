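"""Lumped-parameter models of passive respiratory mechanics.

Two linear models of the ventilated respiratory system are provided.

The viscoelastic model (VEM) is a second-order, two-compartment model in
which the alveolar wall is viscoelastic rather than purely elastic.  Its
state-space form, with airway flow ``V̇`` [mL/s] as input and airway
pressure ``p_aw`` [cmH2O] as output, is

    ṗ_C1 = V̇ / C1
    ṗ_C2 = -p_C2 / (R2·C2) + V̇ / C2
    p_aw = p_C1 + p_C2 + R1·V̇

where ``R1`` [cmH2O·s/mL] is the airway resistance, ``C1`` [mL/cmH2O] the
static compliance, and ``R2``, ``C2`` the resistance and compliance of the
viscoelastic branch, whose product ``τ = R2·C2`` [s] is the viscoelastic
time constant governing the pressure relaxation during a zero-flow hold.

The first-order model (FOM) collapses the viscoelastic branch and keeps a
single resistance ``R`` and compliance ``C``:  ``p_aw = R·V̇ + V/C``.

All quantities use mL, s and cmH2O throughout; no unit conversion happens
inside this module.

Discretisation
--------------
``simulate_vem`` uses the exact zero-order-hold (ZOH) discretisation of the
diagonal state matrix: within each sampling interval the flow sample is
held constant and the states are propagated by the closed-form solution of
the resulting constant-input linear ODE.  For piecewise-constant flow whose
switch points fall on sample boundaries (the volume-controlled-ventilation
profiles used here) this is exact to machine precision, which
``simulate_vem_piecewise_analytic`` exploits as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "VEMParams",
    "FOMParams",
    "Waveform",
    "SimulationState",
    "NOMINAL_PARAMS",
    "DegenerateModelError",
    "NonUniformSamplingError",
    "simulate_vem",
    "simulate_vem_piecewise_analytic",
    "simulate_fom",
    "sse",
]

# Relative tolerance on sample-interval uniformity (fraction of one interval).
UNIFORMITY_RTOL = 1e-9

# Magnitude used to replace non-finite simulated pressures when scoring
# unstable (non-physiological) parameter sets; keeps SSE finite and huge.
_HUGE_PRESSURE = 1e30


class DegenerateModelError(ValueError):
    """Model parameters make the governing equations ill-defined (zero C1, C2 or R2)."""


class NonUniformSamplingError(ValueError):
    """Sample timestamps are not uniformly spaced."""


@dataclass(frozen=True)
class VEMParams:
    """Patient-specific parameters of the viscoelastic model.

    Attributes
    ----------
    R1 : float
        Airway resistance [cmH2O·s/mL].
    C1 : float
        Static compliance [mL/cmH2O].
    R2 : float
        Viscoelastic resistance [cmH2O·s/mL].
    C2 : float
        Viscoelastic compliance [mL/cmH2O].
    """

    R1: float
    C1: float
    R2: float
    C2: float

    def __post_init__(self) -> None:
        for name in ("R1", "C1", "R2", "C2"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)

    @property
    def tau_ve(self) -> float:
        """Viscoelastic time constant R2·C2 [s]."""
        return self.R2 * self.C2

    @property
    def is_physiological(self) -> bool:
        """True iff all four parameters are strictly positive."""
        return self.R1 > 0 and self.C1 > 0 and self.R2 > 0 and self.C2 > 0

    def as_array(self) -> np.ndarray:
        return np.array([self.R1, self.C1, self.R2, self.C2])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "VEMParams":
        R1, C1, R2, C2 = (float(v) for v in x)
        return cls(R1, C1, R2, C2)


#: Realistic physiological parameter set used as the Monte-Carlo nominal.
NOMINAL_PARAMS = VEMParams(R1=0.010, C1=30.00, R2=0.020, C2=80.00)


@dataclass(frozen=True)
class FOMParams:
    """First-order model parameters: airway resistance R and static compliance C."""

    R: float
    C: float

    def __post_init__(self) -> None:
        for name in ("R", "C"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)

    @property
    def is_physiological(self) -> bool:
        return self.R > 0 and self.C > 0


@dataclass(frozen=True)
class SimulationState:
    """Compartment pressures (p_C1, p_C2) [cmH2O] of the VEM at one instant."""

    pC1: float = 0.0
    pC2: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pC1) and np.isfinite(self.pC2)):
            raise ValueError("simulation state must be finite")


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled airway flow / pressure record.

    Attributes
    ----------
    t : ndarray
        Sample times [s], strictly increasing and uniform.
    flow : ndarray
        Airway flow V̇ [mL/s].
    paw : ndarray
        Airway pressure [cmH2O].
    fs : float
        Sampling rate [Hz].
    """

    t: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        flow = np.asarray(self.flow, dtype=float)
        paw = np.asarray(self.paw, dtype=float)
        fs = float(self.fs)
        if fs <= 0 or not np.isfinite(fs):
            raise ValueError(f"fs must be positive and finite, got {fs}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if flow.shape != t.shape or paw.shape != t.shape:
            raise ValueError("t, flow and paw must have equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(flow)) and np.all(np.isfinite(paw))):
            raise ValueError("waveform samples must be finite")
        dt = 1.0 / fs
        dev = np.abs(np.diff(t) - dt)
        if np.any(np.diff(t) <= 0) or np.max(dev) > UNIFORMITY_RTOL * dt:
            row = int(np.argmax(dev)) + 1
            raise NonUniformSamplingError(
                f"timestamps not uniform at 1/fs={dt:g} s (worst at row {row})"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "paw", paw)
        object.__setattr__(self, "fs", fs)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def volume(self) -> np.ndarray:
        """Inspired volume V(t) [mL]: running trapezoidal integral of flow, V(t0)=0."""
        return cumulative_trapezoid(self.flow, dx=1.0 / self.fs, initial=0.0)

    def with_paw(self, paw: np.ndarray) -> "Waveform":
        """Copy of this record with the pressure trace replaced."""
        return Waveform(self.t, self.flow, np.asarray(paw, dtype=float), self.fs)

    @classmethod
    def from_samples(
        cls, flow: np.ndarray, paw: np.ndarray, fs: float, t0: float = 0.0
    ) -> "Waveform":
        flow = np.asarray(flow, dtype=float)
        t = t0 + np.arange(flow.size) / float(fs)
        return cls(t, flow, np.asarray(paw, dtype=float), float(fs))


def _check_vem(params: VEMParams) -> None:
    if params.C1 == 0 or params.C2 == 0 or params.R2 == 0:
        raise DegenerateModelError(
            "VEM requires C1, C2 and R2 nonzero "
            f"(got C1={params.C1}, C2={params.C2}, R2={params.R2})"
        )


def simulate_vem(
    params: VEMParams,
    flow: np.ndarray,
    fs: float,
    initial_state: SimulationState | None = None,
    return_states: bool = False,
):
    """Simulate the VEM pressure response to a sampled flow input.

    The states are propagated with the exact zero-order-hold discretisation:
    the flow sample ``flow[k]`` is held constant on ``[t_k, t_{k+1})`` and

        pC1[k+1] = pC1[k] + flow[k]·dt / C1
        pC2[k+1] = R2·flow[k] + (pC2[k] − R2·flow[k])·exp(−dt/(R2·C2))

    with output ``paw[k] = pC1[k] + pC2[k] + R1·flow[k]``.

    Parameters with negative time constant R2·C2 give an unstable (growing)
    response; the recursion is still well defined and may overflow to ±inf
    for strongly unstable sets — callers scoring such fits should sanitise.

    Returns
    -------
    Waveform, or (Waveform, ndarray of shape (n, 2)) when ``return_states``
    is true; the state array columns are (pC1, pC2).
    """
    _check_vem(params)
    fs = float(fs)
    if fs <= 0:
        raise ValueError("fs must be positive")
    flow = np.asarray(flow, dtype=float)
    if flow.ndim != 1 or flow.size < 2:
        raise ValueError("flow must be a 1-d array with at least 2 samples")
    if not np.all(np.isfinite(flow)):
        raise ValueError("flow must be finite")
    state0 = initial_state or SimulationState()

    n = flow.size
    dt = 1.0 / fs
    tau = params.R2 * params.C2

    pc1 = np.empty(n)
    pc1[0] = state0.pC1
    pc1[1:] = state0.pC1 + np.cumsum(flow[:-1]) * (dt / params.C1)

    # pC2 is a first-order IIR recursion: pC2[k] = a·pC2[k-1] + b·flow[k-1].
    x = np.clip(-dt / tau, -700.0, 700.0)  # avoid exp overflow for tiny |tau|
    a = np.exp(x)
    b = params.R2 * (1.0 - a)
    pc2 = np.empty(n)
    pc2[0] = state0.pC2
    with np.errstate(over="ignore", invalid="ignore"):
        zi = np.array([a * state0.pC2])
        pc2[1:], _ = lfilter([b], [1.0, -a], flow[:-1], zi=zi)
        paw = pc1 + pc2 + params.R1 * flow

    wave = Waveform.from_samples(flow, np.nan_to_num(
        paw, nan=_HUGE_PRESSURE, posinf=_HUGE_PRESSURE, neginf=-_HUGE_PRESSURE
    ) if not np.all(np.isfinite(paw)) else paw, fs)
    if return_states:
        return wave, np.column_stack([pc1, pc2])
    return wave


def simulate_vem_piecewise_analytic(
    params: VEMParams,
    segments: Sequence[tuple[float, float]],
    fs: float = 125.0,
    initial_state: SimulationState | None = None,
) -> Waveform:
    """Closed-form VEM response to piecewise-constant flow (test oracle).

    ``segments`` is a list of ``(duration [s], flow [mL/s])`` pairs.  Within
    a segment of flow F starting from states (pC1⁰, pC2⁰),

        pC1(τ) = pC1⁰ + F·τ/C1
        pC2(τ) = F·R2 + (pC2⁰ − F·R2)·exp(−τ/(R2·C2))
        p_aw   = pC1 + pC2 + R1·F

    and the states are handed continuously across segment boundaries.
    Sampling follows the same convention as :func:`simulate_vem`: sample k
    sits at k/fs and a sample on a boundary belongs to the *new* segment.
    Segment durations must be (near-)integer multiples of 1/fs.
    """
    _check_vem(params)
    fs = float(fs)
    if fs <= 0:
        raise ValueError("fs must be positive")
    state = initial_state or SimulationState()
    tau = params.R2 * params.C2

    t_parts: list[np.ndarray] = []
    flow_parts: list[np.ndarray] = []
    paw_parts: list[np.ndarray] = []
    t_start = 0.0
    pc1_0, pc2_0 = state.pC1, state.pC2
    for duration, F in segments:
        duration = float(duration)
        F = float(F)
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        n_seg = round(duration * fs)
        if abs(n_seg - duration * fs) > 1e-6 or n_seg < 1:
            raise ValueError(
                f"segment duration {duration} s is not a multiple of 1/fs={1 / fs:g} s"
            )
        rel = np.arange(n_seg) / fs  # local time of each sample in the segment
        pc1 = pc1_0 + F * rel / params.C1
        pc2 = F * params.R2 + (pc2_0 - F * params.R2) * np.exp(-rel / tau)
        t_parts.append(t_start + rel)
        flow_parts.append(np.full(n_seg, F))
        paw_parts.append(pc1 + pc2 + params.R1 * F)
        # hand the end-of-segment state to the next segment
        pc1_0 = pc1_0 + F * duration / params.C1
        pc2_0 = F * params.R2 + (pc2_0 - F * params.R2) * np.exp(-duration / tau)
        t_start += duration

    t = np.concatenate(t_parts)
    # rebuild on an exactly uniform grid (concatenation can drift by ulps)
    t = t[0] + np.arange(t.size) / fs
    return Waveform(t, np.concatenate(flow_parts), np.concatenate(paw_parts), fs)


def simulate_fom(params: FOMParams, flow: np.ndarray, fs: float) -> Waveform:
    """Simulate the first-order model: p_aw = R·V̇ + V/C with V = ∫V̇ dt."""
    if params.C == 0:
        raise DegenerateModelError("FOM requires C != 0")
    fs = float(fs)
    if fs <= 0:
        raise ValueError("fs must be positive")
    flow = np.asarray(flow, dtype=float)
    if flow.ndim != 1 or flow.size < 2:
        raise ValueError("flow must be a 1-d array with at least 2 samples")
    volume = cumulative_trapezoid(flow, dx=1.0 / fs, initial=0.0)
    paw = params.R * flow + volume / params.C
    return Waveform.from_samples(flow, paw, fs)


def sse(measured: np.ndarray, simulated: np.ndarray) -> float:
    """Sum of squared errors Σ (measured − simulated)² [(cmH2O)²]."""
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if measured.shape != simulated.shape:
        raise ValueError(
            f"length mismatch: {measured.shape} vs {simulated.shape}"
        )
    with np.errstate(over="ignore", invalid="ignore"):
        r = measured - simulated
        return float(np.dot(r, r))
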