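"""One-shot linear-regression identification of the viscoelastic model.

Eliminating the internal states of the VEM yields a single input–output
relation between airway pressure and flow.  It can be written in a
*derivative* form,

    p_aw = A·ṗ_aw + B·V̈ + C·V̇ + D·V
    A = −R2·C2,  B = R1·R2·C2,  C = (R2·C2 + R2·C1 + R1·C1)/C1,  D = 1/C1

fitted by multiple linear regression (MLR) on numerically differentiated
signals, or — integrating once under p_aw(0) = 0 — in an *integral* form,

    p_aw = A·∫p_aw dt + B·V̇ + C·V + D·∫V dt
    A = −1/(R2·C2),  B = R1,  C = 1/C1 + 1/C2 + R1/(R2·C2),  D = 1/(R2·C1·C2)

fitted by the Integral Method (IM).  Both are solved in least squares via
the Moore–Penrose pseudo-inverse, and the four coefficients map bijectively
back to (R1, C1, R2, C2) wherever the denominators are nonzero.

The derivative form differentiates the measured pressure, which amplifies
measurement noise; the integral form low-pass filters it instead.  That
asymmetry is the point of comparing the two.

Reported SSE is always computed by re-simulating the model with the
recovered parameters against the measured pressure (not from the regression
residuals), so that all identification methods are scored on the same
simulated-versus-measured error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import (
    DegenerateModelError,
    VEMParams,
    Waveform,
    simulate_vem,
    sse,
)

__all__ = [
    "CoefficientVector",
    "FitResult",
    "SingularSystemError",
    "NonRecoverableParametersError",
    "numeric_derivative",
    "cumulative_integral",
    "vem_to_derivative_coeffs",
    "derivative_coeffs_to_vem",
    "vem_to_integral_coeffs",
    "integral_coeffs_to_vem",
    "fit_mlr",
    "fit_im",
    "resimulated_sse",
]


class SingularSystemError(RuntimeError):
    """The regressor matrix is rank deficient."""

    def __init__(self, msg: str, cond: float | None = None):
        super().__init__(msg)
        self.cond = cond


class NonRecoverableParametersError(RuntimeError):
    """Coefficients cannot be mapped back to model parameters (zero denominator)."""

    def __init__(self, msg: str, coeffs: "CoefficientVector"):
        super().__init__(msg)
        self.coeffs = coeffs


@dataclass(frozen=True)
class CoefficientVector:
    """Regression coefficients A–D, tagged by which input–output form they belong to."""

    A: float
    B: float
    C: float
    D: float
    form: Literal["derivative", "integral"]

    def __post_init__(self) -> None:
        for name in "ABCD":
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")
        if self.form not in ("derivative", "integral"):
            raise ValueError(f"unknown form {self.form!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


@dataclass
class FitResult:
    """Outcome of one identification run."""

    params: VEMParams
    coeffs: Optional[CoefficientVector]
    sse: float
    n_iterations: int
    converged: bool
    method: str
    trace: Optional[list[tuple[VEMParams, float]]] = None
    n_fev: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "params": {
                "R1": self.params.R1,
                "C1": self.params.C1,
                "R2": self.params.R2,
                "C2": self.params.C2,
            },
            "is_physiological": self.params.is_physiological,
            "sse": self.sse,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }
        if self.coeffs is not None:
            d["coefficients"] = {
                "A": self.coeffs.A,
                "B": self.coeffs.B,
                "C": self.coeffs.C,
                "D": self.coeffs.D,
                "form": self.coeffs.form,
            }
        if self.n_fev is not None:
            d["n_fev"] = self.n_fev
        return d


# ---------------------------------------------------------------------------
# discrete calculus
# ---------------------------------------------------------------------------

# A sample-to-sample flow change larger than this fraction of the flow range
# is treated as a regime switch (e.g. the inspiration -> pause cut-off).
FLOW_SWITCH_REL_THRESHOLD = 0.2


def flow_switch_intervals(flow: np.ndarray, rel_threshold: float = FLOW_SWITCH_REL_THRESHOLD) -> np.ndarray:
    """Indices k of sample intervals [k, k+1] across which the flow switches regime.

    A ventilator flow profile is piecewise continuous; at a switch the sample
    on the boundary already belongs to the new regime, so discrete calculus
    over the preceding interval must not mix the two regimes (see
    :func:`numeric_derivative` and :func:`cumulative_integral`).  Smooth or
    noisy flows trigger no switches and the plain schemes apply throughout.
    """
    flow = np.asarray(flow, dtype=float)
    rng = np.ptp(flow)
    if rng == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(np.diff(flow)) > rel_threshold * rng)


def numeric_derivative(
    signal: np.ndarray, fs: float, switch_intervals: np.ndarray | None = None
) -> np.ndarray:
    """Numerical time derivative: central differences inside, one-sided at the ends.

    When ``switch_intervals`` marks flow-regime switches, the two samples
    bracketing each switch use forward differences instead: the last
    pre-switch sample differences across the switch (capturing the jump with
    the same quotient in every signal, so jump terms cancel row-wise in the
    regression) and the first post-switch sample differences within the new
    regime only.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    fs = float(fs)
    g = np.gradient(signal, 1.0 / fs)
    if switch_intervals is not None:
        for k in np.asarray(switch_intervals, dtype=int):
            g[k] = (signal[k + 1] - signal[k]) * fs
            if k + 2 < signal.size:
                g[k + 1] = (signal[k + 2] - signal[k + 1]) * fs
    return g


def cumulative_integral(
    signal: np.ndarray, fs: float, switch_intervals: np.ndarray | None = None
) -> np.ndarray:
    """Running trapezoidal integral from the first sample (first value 0).

    Over intervals flagged in ``switch_intervals`` the left-rectangle rule is
    used instead of the trapezoid: the right endpoint sample belongs to the
    new flow regime, and averaging across the discontinuity would inject an
    O(dt) error that persists in the running integral.  For the
    piecewise-constant profiles of volume-controlled ventilation this makes
    the integral of flow (the volume) exact.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    dt = 1.0 / float(fs)
    if switch_intervals is None or len(switch_intervals) == 0:
        return cumulative_trapezoid(signal, dx=dt, initial=0.0)
    inc = (signal[:-1] + signal[1:]) * (0.5 * dt)
    idx = np.asarray(switch_intervals, dtype=int)
    inc[idx] = signal[idx] * dt
    out = np.empty(signal.size)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out


# ---------------------------------------------------------------------------
# coefficient <-> parameter maps
# ---------------------------------------------------------------------------

def vem_to_derivative_coeffs(p: VEMParams) -> CoefficientVector:
    """Forward map (R1, C1, R2, C2) → derivative-form coefficients A–D."""
    tau = p.R2 * p.C2
    return CoefficientVector(
        A=-tau,
        B=p.R1 * tau,
        C=(tau + p.R2 * p.C1 + p.R1 * p.C1) / p.C1,
        D=1.0 / p.C1,
        form="derivative",
    )


def derivative_coeffs_to_vem(c: CoefficientVector) -> VEMParams:
    """Invert the derivative-form coefficient map.

    tau = −A, C1 = 1/D, R1 = −B/A, R2 = C − tau/C1 − R1, C2 = tau/R2.
    """
    if c.form != "derivative":
        raise ValueError("expected derivative-form coefficients")
    if c.A == 0 or c.D == 0:
        raise NonRecoverableParametersError("A and D must be nonzero", c)
    tau = -c.A
    C1 = 1.0 / c.D
    R1 = -c.B / c.A
    R2 = c.C - tau / C1 - R1
    if R2 == 0:
        raise NonRecoverableParametersError("recovered R2 is exactly zero", c)
    C2 = tau / R2
    return VEMParams(R1, C1, R2, C2)


def vem_to_integral_coeffs(p: VEMParams) -> CoefficientVector:
    """Forward map (R1, C1, R2, C2) → integral-form coefficients A–D."""
    tau = p.R2 * p.C2
    return CoefficientVector(
        A=-1.0 / tau,
        B=p.R1,
        C=1.0 / p.C1 + 1.0 / p.C2 + p.R1 / tau,
        D=1.0 / (p.R2 * p.C1 * p.C2),
        form="integral",
    )


def integral_coeffs_to_vem(c: CoefficientVector) -> VEMParams:
    """Invert the integral-form coefficient map.

    tau = −1/A, R1 = B, C1 = −A/D, 1/C2 = C − 1/C1 + A·R1, R2 = tau/C2.
    A negative recovered C2 is *not* an error here; such fits are flagged
    non-physiological downstream but still reported.
    """
    if c.form != "integral":
        raise ValueError("expected integral-form coefficients")
    if c.A == 0 or c.D == 0:
        raise NonRecoverableParametersError("A and D must be nonzero", c)
    tau = -1.0 / c.A
    R1 = c.B
    C1 = -c.A / c.D
    inv_C2 = c.C - 1.0 / C1 + c.A * R1
    if inv_C2 == 0:
        raise NonRecoverableParametersError("recovered 1/C2 is exactly zero", c)
    C2 = 1.0 / inv_C2
    R2 = tau / C2
    return VEMParams(R1, C1, R2, C2)


# ---------------------------------------------------------------------------
# least-squares fits
# ---------------------------------------------------------------------------

def resimulated_sse(params: VEMParams, wave: Waveform) -> float:
    """SSE of the VEM response under ``params`` against the measured pressure.

    Degenerate or wildly unstable parameter sets score +inf / astronomically
    large rather than raising, so method sweeps never abort on a bad fit.
    """
    try:
        sim = simulate_vem(params, wave.flow, wave.fs)
    except DegenerateModelError:
        return float("inf")
    return sse(wave.paw, sim.paw)


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
        raise SingularSystemError(
            f"regressor matrix is rank deficient (rank {rank} of {X.shape[1]})", cond
        )
    return coef


def _apply_mask(X: np.ndarray, y: np.ndarray, mask) -> tuple[np.ndarray, np.ndarray]:
    if mask is None:
        return X, y
    mask = np.asarray(mask)
    return X[mask], y[mask]


def fit_mlr(wave: Waveform, mask: np.ndarray | None = None) -> FitResult:
    """Multiple linear regression on the derivative-form relation.

    Builds the regressor matrix [ṗ_aw, V̈, V̇, V] with ṗ_aw and V̈ from
    central differences (V̈ as the derivative of the flow signal), solves
    the over-determined system by pseudo-inverse, and back-transforms the
    coefficients to (R1, C1, R2, C2).
    """
    if wave.n < 4:
        raise ValueError("need at least 4 samples for a 4-coefficient fit")
    switches = flow_switch_intervals(wave.flow)
    dpaw = numeric_derivative(wave.paw, wave.fs, switches)
    dflow = numeric_derivative(wave.flow, wave.fs, switches)
    V = cumulative_integral(wave.flow, wave.fs, switches)
    X = np.column_stack([dpaw, dflow, wave.flow, V])
    X, y = _apply_mask(X, wave.paw, mask)
    coef = _lstsq(X, y)
    coeffs = CoefficientVector(*coef, form="derivative")
    params = derivative_coeffs_to_vem(coeffs)
    return FitResult(
        params=params,
        coeffs=coeffs,
        sse=resimulated_sse(params, wave),
        n_iterations=0,
        converged=True,
        method="MLR",
    )


def fit_im(wave: Waveform, mask: np.ndarray | None = None) -> FitResult:
    """Integral Method: least squares on the integral-form relation.

    Builds [∫p_aw, V̇, V, ∫V] (running trapezoidal integrals from the first
    sample, assuming p_aw(0) = 0), solves by pseudo-inverse and
    back-transforms.  A fit with negative C2 (or other non-positive
    parameters) is returned and flagged via ``params.is_physiological``.
    """
    if wave.n < 4:
        raise ValueError("need at least 4 samples for a 4-coefficient fit")
    switches = flow_switch_intervals(wave.flow)
    V = cumulative_integral(wave.flow, wave.fs, switches)
    X = np.column_stack(
        [
            cumulative_integral(wave.paw, wave.fs, switches),
            wave.flow,
            V,
            cumulative_integral(V, wave.fs),
        ]
    )
    X, y = _apply_mask(X, wave.paw, mask)
    coef = _lstsq(X, y)
    coeffs = CoefficientVector(*coef, form="integral")
    params = integral_coeffs_to_vem(coeffs)
    return FitResult(
        params=params,
        coeffs=coeffs,
        sse=resimulated_sse(params, wave),
        n_iterations=0,
        converged=True,
        method="IM",
    )
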