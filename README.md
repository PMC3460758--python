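# vemid — viscoelastic respiratory-mechanics model identification

`vemid` identifies the patient-specific parameters of a second-order
**viscoelastic model (VEM)** of passive respiratory mechanics from the two
signals available at the bedside of a mechanically ventilated patient:
airway flow `V̇(t)` [mL/s] and airway pressure `p_aw(t)` [cmH2O].  It is
aimed at researchers in respiratory physiology and model-based ventilation
management who need fast, operator-independent parameter estimates — e.g.
to track viscoelastic tissue properties of ARDS patients breath by breath.

## The model and the methods

The VEM lumps the respiratory system into an airway resistance `R1`
[cmH2O·s/mL], a static compliance `C1` [mL/cmH2O], and a viscoelastic
branch `R2`–`C2` whose time constant `τ = R2·C2` [s] governs the
exponential pressure relaxation during a zero-flow hold:

```
ṗ_C1 = V̇/C1
ṗ_C2 = −p_C2/(R2·C2) + V̇/C2
p_aw = p_C1 + p_C2 + R1·V̇
```

Five identification methods are implemented on top of exact state-space
simulators (`simulate_vem`, plus a closed-form piecewise-constant-flow
oracle and a first-order model `p_aw = R·V̇ + V/C`):

| method | idea |
|--------|------|
| **MLR** | least squares on the derivative form `p_aw = A·ṗ_aw + B·V̈ + C·V̇ + D·V` |
| **IM**  | least squares on the integral form `p_aw = A·∫p_aw + B·V̇ + C·V + D·∫V` |
| **IIM** | repeat the IM, rebuilding the `∫p_aw` regressor from the *re-simulated* model pressure each iteration until the SSE change falls below `TolFun = 1e-4` |
| **SSM** | Nelder–Mead simplex minimisation of the re-simulation SSE |
| **LMA** | Levenberg–Marquardt on the pressure residual vector |

All four coefficients of either linear form map bijectively back to
`(R1, C1, R2, C2)`.  MLR differentiates the measured pressure and amplifies
noise; the IM integrates and is robust, but un-modelled disturbances can
push it to non-physiological values (e.g. negative `C2`); the IIM keeps the
IM's speed and initial-value independence while converging to the same
error minimum as the simplex search.  The SSM/LMA optimisers are seeded
either with known generating values (simulation studies) or by a
hierarchical scheme: first-order-model regression for `R1`, `C1` plus an
exponential fit of the end-inspiratory-pause decay for `τ`.

A synthetic-data module generates the volume-controlled-ventilation study
corpus (constant 500 mL/s for 1 s, 4 s pause, 125 Hz; parameters uniform in
0.5–1.5× the nominal set `R1=0.010, C1=30.00, R2=0.020, C2=80.00`; 5%
white pressure noise), and a benchmark module runs all methods over it.

## Worked example

Simulate a noise-free breath for a "patient" with `R1=0.012, C1=25,
R2=0.025, C2=90`, add 5% measurement noise, and identify:

```bash
vemid simulate --params 0.012,25,0.025,90 -o wave.csv
# (add noise, e.g. via vemid.add_noise in Python)
vemid identify -i wave_noisy.csv --method iim
```

```json
{
  "method": "IIM",
  "params": {"R1": 0.01205, "C1": 25.15, "R2": 0.02690, "C2": 87.58},
  "is_physiological": true,
  "sse": 705.98,
  "n_iterations": 1,
  "converged": true
}
```

The IIM converges in a single iteration and recovers the generating
parameters to within a few percent despite the noise; the reported SSE
(≈706 (cmH2O)², i.e. ≈1.06 cmH2O RMS over 625 samples) is the noise floor.
The same record identified with `--method mlr` returns
`R1 = −0.190, C2 = 0.0005` (`"is_physiological": false`) with SSE 21189 —
the noise-amplified derivative regression fails exactly as expected, which
is why the integral methods exist.

Python API equivalent:

```python
import vemid as v
flow = v.vcv_flow_profile(500, 1, 4, 125)
wave = v.simulate_vem(v.VEMParams(0.012, 25, 0.025, 90), flow, 125)
noisy = wave.with_paw(v.add_noise(wave.paw, 0.05, seed=11))
fit = v.fit_iim(noisy)           # no initial guess needed
print(fit.params, fit.sse, fit.n_iterations)
```

The full Monte-Carlo comparison (`vemid benchmark -o report/`) writes a
tidy CSV of per-method correlations, SSE statistics and iteration counts.

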