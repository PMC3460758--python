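"""Iterative Integral Method (IIM).

The IIM repeats the integral regression of :func:`vemid.regression.fit_im`,
but after each solve the model pressure is re-simulated from the current
parameter estimate and the ∫p_aw regressor column is rebuilt from that
*simulated* pressure, while the right-hand-side target stays the *measured*
pressure.  The linear solve therefore progressively optimises the simulated
response against the measurement directly, which (a) removes the dependence
on the noisy measured pressure inside the regressors, and (b) requires no
initial parameter guess — iteration 0 is exactly the Integral Method.

Intermediate iterations may produce non-physiological parameter values
(e.g. a negative C2); these are not errors — the linear ODE remains well
defined and subsequent iterations typically recover, which is precisely the
behaviour that makes the method robust to un-modelled disturbances.

Convergence is declared when the relative change of the re-simulation SSE
between consecutive iterations falls below ``tol_fun`` (default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import DegenerateModelError, Waveform, simulate_vem, sse
from .regression import (
    CoefficientVector,
    FitResult,
    NonRecoverableParametersError,
    SingularSystemError,
    _lstsq,
    cumulative_integral,
    fit_im,
    flow_switch_intervals,
    integral_coeffs_to_vem,
    resimulated_sse,
)

__all__ = ["IIMConfig", "IterationFailureError", "fit_iim", "sse"]

# consecutive SSE increases tolerated before declaring divergence
_DIVERGENCE_PATIENCE = 10


class IterationFailureError(RuntimeError):
    """The iteration could not continue; carries the trace accumulated so far."""

    def __init__(self, msg: str, trace: list):
        super().__init__(msg)
        self.trace = trace


@dataclass(frozen=True)
class IIMConfig:
    """Iteration controls for the IIM.

    tol_fun : relative SSE-change termination tolerance (default 1e-4, the
        conventional TolFun value); may be +inf to force a single solve.
    max_iterations : hard cap on solves after iteration 0.
    on_invalid_params : what to do when an iteration yields non-physiological
        parameters — ``continue`` (default; keep iterating, matching the
        observed self-correction of the method) or ``abort`` (stop and return
        the flagged result).
    """

    tol_fun: float = 1e-4
    max_iterations: int = 100
    on_invalid_params: Literal["continue", "abort"] = "continue"

    def __post_init__(self) -> None:
        if not self.tol_fun > 0:
            raise ValueError("tol_fun must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.on_invalid_params not in ("continue", "abort"):
            raise ValueError(f"unknown policy {self.on_invalid_params!r}")


def fit_iim(wave: Waveform, cfg: IIMConfig | None = None) -> FitResult:
    """Identify VEM parameters by the Iterative Integral Method.

    Iteration 0 is exactly :func:`fit_im`.  Each subsequent iteration
    re-simulates p_aw from the current parameters, rebuilds the ∫p_aw
    column from the simulated pressure, re-solves the least-squares system
    against the measured pressure, and evaluates the re-simulation SSE.
    The trace records every iteration's (params, sse).

    Note the signature: there is no initial parameter guess — independence
    from initial values is a structural property of the method.
    """
    cfg = cfg or IIMConfig()

    res0 = fit_im(wave)
    trace: list[tuple] = [(res0.params, res0.sse)]

    def result(params, coeffs, s, n_it, converged):
        return FitResult(
            params=params,
            coeffs=coeffs,
            sse=s,
            n_iterations=n_it,
            converged=converged,
            method="IIM",
            trace=list(trace),
        )

    if res0.sse == 0.0:
        # perfect fit already at iteration 0
        return result(res0.params, res0.coeffs, 0.0, 0, True)
    if not np.isfinite(cfg.tol_fun):
        # degenerate tolerance: any change is accepted, so a single solve suffices
        return result(res0.params, res0.coeffs, res0.sse, 0, True)
    if cfg.on_invalid_params == "abort" and not res0.params.is_physiological:
        return result(res0.params, res0.coeffs, res0.sse, 0, False)

    # fixed right-hand-side columns and target
    switches = flow_switch_intervals(wave.flow)
    V = cumulative_integral(wave.flow, wave.fs, switches)
    flow_col = wave.flow
    intV = cumulative_integral(V, wave.fs)
    y = wave.paw

    params, coeffs, sse_prev = res0.params, res0.coeffs, res0.sse
    best_idx = 0
    n_increases = 0
    converged = False
    n_it = 0
    for n_it in range(1, cfg.max_iterations + 1):
        try:
            sim = simulate_vem(params, wave.flow, wave.fs)
        except DegenerateModelError as exc:
            raise IterationFailureError(f"re-simulation failed: {exc}", trace) from exc
        int_paw = cumulative_integral(sim.paw, wave.fs, switches)
        X = np.column_stack([int_paw, flow_col, V, intV])
        try:
            coef = _lstsq(X, y)
        except SingularSystemError as exc:
            raise IterationFailureError(f"singular system at iteration {n_it}", trace) from exc
        coeffs = CoefficientVector(*coef, form="integral")
        try:
            params = integral_coeffs_to_vem(coeffs)
        except NonRecoverableParametersError as exc:
            raise IterationFailureError(
                f"non-recoverable coefficients at iteration {n_it}", trace
            ) from exc
        sse_k = resimulated_sse(params, wave)
        trace.append((params, sse_k))
        if not np.isfinite(sse_k) or sse_k > 1e20:
            # iterate blew up (strongly unstable parameters): return best-so-far
            p_best, s_best = trace[best_idx]
            return result(p_best, coeffs, s_best, n_it, False)
        if sse_k <= trace[best_idx][1]:
            best_idx = len(trace) - 1

        if sse_k == 0.0 or abs(sse_k - sse_prev) / sse_prev < cfg.tol_fun:
            converged = True
            break
        # only a *significant* increase (beyond tol_fun relative) counts toward
        # divergence; sub-tolerance wobble is normal near a fixed point
        n_increases = n_increases + 1 if sse_k > sse_prev * (1.0 + cfg.tol_fun) else 0
        if n_increases >= _DIVERGENCE_PATIENCE:
            # diverging: return the best iterate seen so far, flagged
            p_best, s_best = trace[best_idx]
            return result(p_best, coeffs, s_best, n_it, False)
        sse_prev = sse_k
        if cfg.on_invalid_params == "abort" and not params.is_physiological:
            return result(params, coeffs, sse_k, n_it, False)

    return result(params, coeffs, trace[-1][1], n_it, converged)
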