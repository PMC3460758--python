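# Methods

## Model

The viscoelastic model (VEM) is a linear, time-invariant two-compartment
lumped model of the passive respiratory system.  Airway flow `V̇` [mL/s]
drives two internal pressures: `p_C1 = V/C1`, the elastic recoil of the
static compartment, and `p_C2`, the stress borne by a viscoelastic
(Maxwell-body) branch that relaxes with time constant `τ = R2·C2`:

    ṗ_C1 = V̇/C1
    ṗ_C2 = −p_C2/(R2·C2) + V̇/C2
    p_aw  = p_C1 + p_C2 + R1·V̇

Units are fixed to mL, s, cmH2O throughout.  The first-order model (FOM)
`p_aw = R·V̇ + V/C` is the `R2 → 0` limit and is used only to seed the
optimisers.  Assumptions inherited from the model class: linearity (no
recruitment/over-distension, no flow limitation), passive patient (no
spontaneous effort), and a zero pressure baseline — records carrying a
PEEP offset should be baseline-corrected before identification, or a
nonzero initial state passed to the simulator.  A strictly positive
parameter set is "physiological"; fits are flagged, never silently
rejected, when any parameter comes out non-positive.

## Simulation

`simulate_vem` uses the exact zero-order-hold (ZOH) discretisation: the
state matrix is diagonal, so each sampling interval has a closed-form
update (`p_C1` accumulates `V̇·dt/C1`; `p_C2` relaxes toward `R2·V̇` with
factor `e^(−dt/τ)`), implemented as a first-order IIR recursion.  For
piecewise-constant flow whose switch instants fall on sample boundaries —
every profile generated here — this is *exact*, which
`simulate_vem_piecewise_analytic` (independent closed-form evaluation,
used as the test oracle) confirms to machine precision.  There is no ODE
solver tolerance anywhere.  Unstable parameter sets (negative `τ`) are
simulated as-is; outputs that overflow are sanitised to ±1e30 only where a
fit is being *scored*, so that method sweeps rank a divergent fit as
astronomically bad rather than crashing.

## Identification

Eliminating the states gives one input–output relation in two equivalent
forms, each linear in four coefficients `A–D` that map bijectively to
`(R1, C1, R2, C2)` (both maps and inverses are property-tested):

* derivative form (MLR): `p_aw = A·ṗ_aw + B·V̈ + C·V̇ + D·V`,
  `A = −R2C2`, `B = R1R2C2`, `C = (R2C2 + R2C1 + R1C1)/C1`, `D = 1/C1`;
* integral form (IM, p_aw(0) = 0): `p_aw = A·∫p_aw + B·V̇ + C·V + D·∫V`,
  `A = −1/(R2C2)`, `B = R1`, `C = 1/C1 + 1/C2 + R1/(R2C2)`,
  `D = 1/(R2C1C2)`.

Both are solved by pseudo-inverse least squares over the full record
(optionally masked).  Reported SSE is **always** the sum of squared
differences between the measured pressure and a full re-simulation with
the recovered parameters — never the regression residual — so all five
methods are scored on the same quantity.

The IIM re-simulates `p_aw` from the current estimate, rebuilds the
`∫p_aw` regressor column from that simulated pressure (the right-hand-side
target stays the measurement), re-solves, and repeats until the relative
SSE change drops below `tol_fun` (default 1e-4, conventional TolFun
semantics against the *previous* iteration).  Iteration 0 is exactly the
IM; the method takes no initial guess by construction.  Non-physiological
intermediate estimates are legitimate iterates (the linear ODE is well
defined for negative parameters) and typically self-correct within a few
iterations.  Safety nets the basic scheme needs in practice: a
`max_iterations` cap (default 100); immediate convergence if the iteration-0
fit is already exact; divergence detection (ten consecutive SSE increases
each exceeding `tol_fun` relative — sub-tolerance wobble near the fixed
point must not count — returns the best iterate, flagged not-converged);
and an explosion guard (SSE above 1e20 stops the iteration the same way).

### Discrete calculus at flow-regime switches

Ventilator flow is piecewise continuous with near-instantaneous switches
(inspiration cut-off, occlusion onset).  A sample on a switch instant
belongs to the new regime, so plain central differences and trapezoidal
quadrature mix the two regimes over the bracketing interval and inject
O(dt) errors with very high leverage — enough to bias noise-free `R2`
recovery by ~17% at 125 Hz and to prevent the IIM settling.  The fits
therefore detect switches (a sample-to-sample flow change exceeding 20% of
the flow range; smooth or noisy flow triggers nothing) and locally refine:
left-rectangle quadrature over the switch interval (which makes the
integrated volume of a constant-flow inflation exact) and matched forward
differences on the two bracketing samples, so the pressure jump `R1·ΔV̇`
cancels row-wise against the flow-derivative column.  With this, noise-free
recovery is ≤ ~1e-4 relative at 125 Hz for MLR and IM alike, tightening to
≤ 1e-6 at refined sampling rates.  Away from switches the schemes are the
conventional ones: `np.gradient` central differences (second derivatives
taken as the derivative of the flow signal, preserving the
noise-amplification behaviour that distinguishes MLR) and cumulative
trapezoid from the first sample.

### Optimisers and hierarchical initialization

SSM is scipy's Nelder–Mead, LMA scipy's `least_squares(method="lm")` with
a numerical Jacobian, both over parameters normalised by the initial
estimate so the termination tolerances (default 1e-4, `max_evals` 10 000)
act as relative changes; the SSM function tolerance is additionally scaled
by the initial SSE.  Initial values come either from the generating
parameters (simulation protocol) or hierarchically: FOM regression gives
`R1`, `C1`; the exponential fit of the pressure decay in the detected
zero-flow window (|flow| < 1% of peak for ≥ 0.2 s; first 3 samples skipped
to avoid the cut-off transient; decays below 0.1% of the pressure range
are rejected as uninformative) gives `τ`.  Only the product `R2·C2` is
identifiable from the decay, so the split is seeded as `C2 = 2·C1`
(viscoelastic compliance typically exceeds static), `R2 = τ/C2`; the
factor is configurable and only affects the optimiser's starting point.

## Synthetic data and the Monte-Carlo benchmark

The generator's defaults are the study conditions: VCV profile of
500 mL/s for 1 s followed by a 4 s end-inspiratory pause at 125 Hz (the
clinical recording rate); 100 parameter sets with each of the four
parameters drawn independently and uniformly in 0.5–1.5× the nominal set
`R1=0.010, C1=30.00, R2=0.020, C2=80.00`; 10 noise realisations per set.
"5% white noise" is read as zero-mean Gaussian with per-sample SD equal to
5% of the clean sample magnitude (noise therefore also covers the pause,
and a zero signal stays zero); a uniform ±5% alternative is selectable for
sensitivity analysis.  Randomness is structured as one master seed with
per-(parameter set, noise set) child streams, so any dataset is
regenerable in isolation, and the whole corpus is a pure function of its
config.  An occluded-inflation generator (`scass_like_waveform`) produces
clinically shaped single-step records for disturbance fixtures.

The benchmark runs every method on every dataset; on noisy data the
per-dataset reference minimum is the simplex-search solution and a
method's degradation is the median of `100·(SSE_method − SSE_SSM)/SSE_SSM`.
Under these conditions the MLR's median degradation comes out in the
~2000% range: roughly a fifth of its fits land on unstable (negative-τ)
parameter sets whose re-simulation error is astronomically large.  The
precise figure is sensitive to the noise-realisation model (distribution
and scaling of the "5%"), so it should be read as an order of magnitude —
the robust findings, stable across seeds, are that MLR degrades by
hundreds-to-thousands of percent while IM, IIM, SSM and LMA sit within a
fraction of a percent of the same minimum, and that the IIM converges at
its first iteration on this corpus (median and modal iteration count 1).

What the synthetic corpus does *not* emulate: cardiogenic oscillations,
spontaneous-effort artifacts, sensor drift, PEEP baselines, and nonlinear
mechanics.  Passing tests on this corpus therefore demonstrate correctness
and noise robustness of the identification machinery, not clinical
validity on real ARDS recordings.  The disturbance fixtures (a localized
pressure artifact on an occluded inflation) probe the un-modelled-effect
regime qualitatively: the one-shot IM lands on a negative `C2`, the IIM
walks back to physiological values at the simplex minimum with a
non-increasing SSE trace.

## Numerical and scale choices

* Waveforms must be uniformly sampled (tolerance 1e-9 of one interval);
  volume is the running trapezoid of flow with `V(t0) = 0`.
* Rank-deficient regressor matrices raise a diagnosable error carrying the
  condition estimate; exactly-zero back-transform denominators raise a
  non-recoverable-parameters error that still carries the coefficients.
* Test and acceptance runs use the full study sizes (100 sets, 1000 noisy
  datasets); the whole suite completes in about a minute on one CPU, so no
  scaled-down variants are needed.
* CSV I/O keeps 12 significant digits; wall-clock timing is deliberately
  never asserted anywhere.
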