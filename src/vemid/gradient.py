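"""Gradient / direct-search reference methods and hierarchical initialization.

Two error-mapping optimisers minimise the re-simulation SSE over the four
VEM parameters: a Nelder–Mead simplex search (SSM) and Levenberg–Marquardt
(LMA) on the pressure residual vector.  Both need an initial estimate; a
hierarchical scheme supplies one from simpler fits:

1. the first-order model p_aw = R·V̇ + V/C is identified by linear
   regression, giving R and C;
2. the exponential pressure drop during the zero-flow phase is fitted to
   estimate its time constant τ, which under the model equals R2·C2;
3. the VEM initial estimate is assembled as R1 = R, C1 = C, C2 = k·C1
   (default k = 2; only the product R2·C2 is identifiable from the decay,
   so the split merely seeds the optimiser) and R2 = τ/C2.

Both optimisers work on parameters normalised by the initial estimate, so
the termination tolerances (default 1e-4) act as *relative* changes in the
parameters, and the SSE tolerance is scaled by the initial SSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize

from .model import (
    DegenerateModelError,
    FOMParams,
    VEMParams,
    Waveform,
    simulate_vem,
    sse,
)
from .regression import FitResult, SingularSystemError, _lstsq

__all__ = [
    "InitialEstimate",
    "OptimizerConfig",
    "FitFailureError",
    "InitializationFailureError",
    "fit_fom_mlr",
    "detect_zero_flow_window",
    "estimate_tau",
    "hierarchical_init",
    "fit_ssm",
    "fit_lma",
]

_HUGE = 1e8  # residual magnitude substituted for non-finite simulated pressure


class FitFailureError(RuntimeError):
    """A nonlinear sub-fit (exponential decay) failed."""


class InitializationFailureError(RuntimeError):
    """No usable zero-flow phase; hierarchical initialization impossible."""


@dataclass(frozen=True)
class InitialEstimate:
    """Hierarchically assembled starting point for the VEM optimisers."""

    fom: FOMParams
    tau: float            # estimated viscoelastic time constant [s]
    vem_init: VEMParams


@dataclass(frozen=True)
class OptimizerConfig:
    """Termination controls shared by SSM and LMA (relative tolerances)."""

    tol_x: float = 1e-4
    tol_fun: float = 1e-4
    max_evals: int = 10_000

    def __post_init__(self) -> None:
        if not (self.tol_x > 0 and self.tol_fun > 0):
            raise ValueError("tolerances must be > 0")
        if self.max_evals < 1:
            raise ValueError("max_evals must be >= 1")


def fit_fom_mlr(wave: Waveform) -> FOMParams:
    """Identify the first-order model by linear regression: p_aw = R·V̇ + (1/C)·V."""
    X = np.column_stack([wave.flow, wave.volume()])
    try:
        coef = _lstsq(X, wave.paw)
    except SingularSystemError:
        raise
    R, invC = coef
    if invC == 0:
        raise SingularSystemError("recovered 1/C is exactly zero")
    return FOMParams(R=float(R), C=float(1.0 / invC))


def detect_zero_flow_window(
    wave: Waveform, rel_threshold: float = 0.01, min_duration_s: float = 0.2
) -> slice:
    """Longest contiguous run of samples with |flow| below ``rel_threshold``
    times the peak |flow|, lasting at least ``min_duration_s``."""
    thr = rel_threshold * np.max(np.abs(wave.flow))
    low = np.abs(wave.flow) <= thr
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(np.append(low, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if best_len < max(2, int(round(min_duration_s * wave.fs))):
        raise InitializationFailureError("no zero-flow phase detected")
    return slice(best_start, best_start + best_len)


def estimate_tau(wave: Waveform, window: slice | None = None, skip: int = 3) -> float:
    """Estimate the relaxation time constant from the zero-flow pressure decay.

    Fits p_aw(t) = p_inf + a·exp(−(t−t0)/τ) over the window by nonlinear
    least squares (initialised from a log-linear fit with p_inf taken from
    the window tail).  The first ``skip`` samples of an auto-detected window
    are dropped to avoid the flow cut-off transient.
    """
    if window is None:
        window = detect_zero_flow_window(wave)
        window = slice(window.start + skip, window.stop)
    t = wave.t[window]
    p = wave.paw[window]
    if t.size < 5:
        raise ValueError("window must contain at least 5 samples")
    if np.max(np.abs(wave.flow[window])) > 0.05 * np.max(np.abs(wave.flow)):
        raise ValueError("window must lie within a zero-flow phase")

    n_tail = max(3, t.size // 10)
    p_inf0 = float(np.mean(p[-n_tail:]))
    resid0 = p - p_inf0
    # a decay smaller than 0.1% of the record's pressure range carries no
    # usable viscoelastic information (it would fit numerical residue)
    if resid0[0] <= 1e-3 * np.ptp(wave.paw):
        raise FitFailureError("window shows no decaying pressure")
    # log-linear seed on the early (positive) part of the decay
    pos = resid0 > max(1e-12, 0.05 * resid0[0])
    if np.count_nonzero(pos) >= 3:
        slope = np.polyfit(t[pos], np.log(resid0[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0

    def model(tt, p_inf, a, tau):
        return p_inf + a * np.exp(-(tt - t[0]) / tau)

    try:
        popt, _ = curve_fit(
            model, t, p, p0=[p_inf0, resid0[0], tau0], maxfev=10_000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc
    _, a, tau = popt
    if a <= 0 or tau <= 0:
        raise FitFailureError(
            f"fitted decay is not a positive exponential (a={a:g}, tau={tau:g})"
        )
    return float(tau)


def hierarchical_init(wave: Waveform, c2_over_c1: float = 2.0) -> InitialEstimate:
    """Assemble a VEM starting point from the FOM fit and the EIP decay."""
    fom = fit_fom_mlr(wave)
    try:
        tau = estimate_tau(wave)
    except (FitFailureError, InitializationFailureError, ValueError) as exc:
        raise InitializationFailureError(
            f"viscoelastic time-constant estimate failed: {exc}"
        ) from exc
    C2 = c2_over_c1 * fom.C
    vem_init = VEMParams(R1=fom.R, C1=fom.C, R2=tau / C2, C2=C2)
    return InitialEstimate(fom=fom, tau=tau, vem_init=vem_init)


def _objective_factory(wave: Waveform, scale: np.ndarray):
    """Residual / SSE of the re-simulated pressure for normalised parameters x."""

    def residuals(x: np.ndarray) -> np.ndarray:
        p = x * scale
        try:
            sim = simulate_vem(VEMParams.from_array(p), wave.flow, wave.fs)
        except (DegenerateModelError, ValueError, OverflowError):
            return np.full(wave.n, _HUGE)
        r = wave.paw - sim.paw
        return np.nan_to_num(r, nan=_HUGE, posinf=_HUGE, neginf=-_HUGE)

    def objective(x: np.ndarray) -> float:
        r = residuals(x)
        return float(np.dot(r, r))

    return residuals, objective


def _prepare(init: VEMParams):
    x0 = init.as_array()
    if not np.all(np.isfinite(x0)):
        raise ValueError("initial estimate must be finite")
    scale = np.abs(x0)
    scale[scale == 0] = 1.0
    return x0 / scale, scale


def fit_ssm(
    wave: Waveform, init: VEMParams, cfg: OptimizerConfig | None = None
) -> FitResult:
    """Nelder–Mead simplex minimisation of the re-simulation SSE."""
    cfg = cfg or OptimizerConfig()
    x0, scale = _prepare(init)
    _, objective = _objective_factory(wave, scale)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is non-finite at the initial estimate")
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": cfg.tol_x,
            "fatol": cfg.tol_fun * max(f0, 1e-30),
            "maxfev": cfg.max_evals,
            "adaptive": False,
        },
    )
    params = VEMParams.from_array(res.x * scale)
    return FitResult(
        params=params,
        coeffs=None,
        sse=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        method="SSM",
        n_fev=int(res.nfev),
    )


def fit_lma(
    wave: Waveform, init: VEMParams, cfg: OptimizerConfig | None = None
) -> FitResult:
    """Levenberg–Marquardt minimisation of the pressure residual vector."""
    cfg = cfg or OptimizerConfig()
    x0, scale = _prepare(init)
    residuals, _ = _objective_factory(wave, scale)
    r0 = residuals(x0)
    if not np.all(np.isfinite(r0)):
        raise ValueError("residuals are non-finite at the initial estimate")
    res = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=cfg.tol_x,
        ftol=cfg.tol_fun,
        max_nfev=cfg.max_evals,
    )
    params = VEMParams.from_array(res.x * scale)
    return FitResult(
        params=params,
        coeffs=None,
        sse=float(2.0 * res.cost),
        n_iterations=int(res.nfev),
        converged=bool(res.status > 0),
        method="LMA",
        n_fev=int(res.nfev),
    )
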