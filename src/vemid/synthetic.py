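"""Synthetic ventilation data: VCV profiles, random parameter sets, noisy corpora.

The Monte-Carlo study conditions are: a volume-controlled-ventilation (VCV)
inflation of 500 mL/s held for 1 s followed by a 4 s end-inspiratory pause
(EIP), applied to viscoelastic models whose four parameters are drawn
independently and uniformly between 0.5 and 1.5 times the nominal set
(R1=0.010, C1=30.00, R2=0.020, C2=80.00), sampled at 125 Hz; each clean
pressure response receives 10 independent realisations of white noise with
per-sample standard deviation equal to 5% of the clean sample magnitude.
These are the defaults of :class:`MonteCarloConfig`.

Randomness is structured so any single dataset is regenerable in isolation:
one master seed; the parameter draw uses the child stream ``(seed,)`` and
the noise of (parameter set i, noise set j) uses ``(seed, i, j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import (
    NOMINAL_PARAMS,
    SimulationState,
    VEMParams,
    Waveform,
    simulate_vem,
)

__all__ = [
    "MonteCarloConfig",
    "LabeledDataset",
    "vcv_flow_profile",
    "draw_parameter_sets",
    "add_noise",
    "generate_monte_carlo",
    "scass_like_waveform",
]


@dataclass(frozen=True)
class MonteCarloConfig:
    """Configuration of the Monte-Carlo simulation study (defaults = study conditions)."""

    n_param_sets: int = 100
    n_noise_sets: int = 10
    nominal: VEMParams = NOMINAL_PARAMS
    range_lo: float = 0.5
    range_hi: float = 1.5
    noise_fraction: float = 0.05
    noise_distribution: Literal["gaussian", "uniform"] = "gaussian"
    fs: float = 125.0
    inspiration_s: float = 1.0
    eip_s: float = 4.0
    insp_flow: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_param_sets < 1:
            raise ValueError("n_param_sets must be >= 1")
        if self.n_noise_sets < 0:
            raise ValueError("n_noise_sets must be >= 0")
        if not (0 < self.range_lo <= self.range_hi):
            raise ValueError("require 0 < range_lo <= range_hi")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.noise_distribution not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise distribution {self.noise_distribution!r}")


@dataclass(frozen=True)
class LabeledDataset:
    """One synthetic record: the generating parameters plus clean and noisy pressure."""

    true_params: VEMParams
    waveform: Waveform          # flow + (possibly noisy) pressure
    clean_paw: np.ndarray       # noise-free pressure, same length
    param_set_id: int
    noise_set_id: int           # 0 is reserved for the noise-free copy

    def __post_init__(self) -> None:
        if self.clean_paw.shape != self.waveform.paw.shape:
            raise ValueError("clean_paw must match the waveform length")


def vcv_flow_profile(
    insp_flow: float, inspiration_s: float, eip_s: float, fs: float
) -> np.ndarray:
    """Constant-flow VCV inspiration followed by a zero-flow end-inspiratory pause.

    Returns the sampled flow [mL/s]: ``insp_flow`` for t in [0, inspiration_s),
    0 during the pause; samples sit at k/fs for k = 0 .. round((Ti+Te)·fs)−1.
    """
    if inspiration_s <= 0 or eip_s <= 0:
        raise ValueError("durations must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n_insp = round(inspiration_s * fs)
    n_eip = round(eip_s * fs)
    if n_insp < 1 or n_eip < 1:
        raise ValueError("durations must cover at least one sample each")
    flow = np.zeros(n_insp + n_eip)
    flow[:n_insp] = float(insp_flow)
    return flow


def draw_parameter_sets(cfg: MonteCarloConfig) -> list[VEMParams]:
    """Draw ``cfg.n_param_sets`` parameter sets, each coordinate uniform in
    [range_lo·nominal, range_hi·nominal], independently per parameter."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed,)))
    nominal = cfg.nominal.as_array()
    lo = cfg.range_lo * nominal
    hi = cfg.range_hi * nominal
    draws = rng.uniform(lo, hi, size=(cfg.n_param_sets, 4))
    return [VEMParams.from_array(row) for row in draws]


def add_noise(
    paw: np.ndarray,
    noise_fraction: float,
    seed,
    distribution: Literal["gaussian", "uniform"] = "gaussian",
) -> np.ndarray:
    """Add per-sample white measurement noise scaled to the local signal level.

    ``gaussian``: zero-mean normal with SD = noise_fraction·|paw[i]|.
    ``uniform``: uniform on ±noise_fraction·|paw[i]|.
    ``seed`` may be an int, a SeedSequence or a Generator.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    paw = np.asarray(paw, dtype=float)
    if noise_fraction == 0:
        return paw.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = noise_fraction * np.abs(paw)
    if distribution == "gaussian":
        return paw + rng.standard_normal(paw.size) * scale
    if distribution == "uniform":
        return paw + rng.uniform(-1.0, 1.0, paw.size) * scale
    raise ValueError(f"unknown noise distribution {distribution!r}")


def generate_monte_carlo(cfg: MonteCarloConfig) -> list[LabeledDataset]:
    """Generate the full Monte-Carlo corpus as a pure function of ``cfg``.

    For each drawn parameter set the VCV response is simulated once; the
    returned list holds the noise-free copy (noise_set_id 0) followed by
    ``cfg.n_noise_sets`` independent noisy copies (ids 1..n), for every
    parameter set in order.
    """
    flow = vcv_flow_profile(cfg.insp_flow, cfg.inspiration_s, cfg.eip_s, cfg.fs)
    datasets: list[LabeledDataset] = []
    for pid, params in enumerate(draw_parameter_sets(cfg)):
        clean = simulate_vem(params, flow, cfg.fs)
        datasets.append(
            LabeledDataset(params, clean, clean.paw.copy(), pid, 0)
        )
        for nid in range(1, cfg.n_noise_sets + 1):
            noisy = add_noise(
                clean.paw,
                cfg.noise_fraction,
                np.random.SeedSequence((cfg.seed, pid, nid)),
                cfg.noise_distribution,
            )
            datasets.append(
                LabeledDataset(params, clean.with_paw(noisy), clean.paw.copy(), pid, nid)
            )
    return datasets


def scass_like_waveform(
    params: VEMParams,
    occlusion_volume: float,
    insp_flow: float = 500.0,
    fs: float = 125.0,
    occlusion_s: float = 4.0,
    max_inspiration_s: float = 2.0,
) -> LabeledDataset:
    """Constant-flow inflation occluded once a target inspired volume is reached.

    Emulates the shape of a SCASS manoeuvre (static compliance automated
    single step): flow is cut to zero when the cumulative volume reaches
    ``occlusion_volume`` [mL]; during the occlusion the pressure relaxes
    exponentially (time constant R2·C2) toward the quasi-static plateau
    ``occlusion_volume / C1``.
    """
    if insp_flow <= 0 or occlusion_volume <= 0:
        raise ValueError("insp_flow and occlusion_volume must be positive")
    t_occ = occlusion_volume / insp_flow
    if t_occ > max_inspiration_s:
        raise ValueError(
            f"occlusion volume {occlusion_volume} mL unreachable within "
            f"{max_inspiration_s} s at {insp_flow} mL/s"
        )
    n_insp = round(t_occ * fs)
    if abs(n_insp - t_occ * fs) > 1e-6:
        # snap to the next sample; the delivered volume is flow * n/fs
        n_insp = int(np.ceil(t_occ * fs - 1e-9))
    if n_insp < 1:
        raise ValueError("occlusion volume reached before the first sample")
    n_occ = round(occlusion_s * fs)
    if n_occ < 1:
        raise ValueError("occlusion_s must cover at least one sample")
    flow = np.zeros(n_insp + n_occ)
    flow[:n_insp] = float(insp_flow)
    wave = simulate_vem(params, flow, fs)
    return LabeledDataset(params, wave, wave.paw.copy(), 0, 0)
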