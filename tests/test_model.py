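"""Viscoelastic and first-order model simulators against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vemid as v

FS = 125.0


def test_constant_flow_matches_closed_form(nominal):
    """paw(t) = R1·F + F·t/C1 + F·R2·(1 − e^(−t/τ)) for constant flow from rest."""
    F, T = 500.0, 1.0
    flow = np.full(int(T * FS) + 1, F)  # includes the sample at t = 1 s
    wave = v.simulate_vem(nominal, flow, FS)
    t = wave.t
    tau = nominal.tau_ve
    expected = nominal.R1 * F + F * t / nominal.C1 + F * nominal.R2 * (1 - np.exp(-t / tau))
    np.testing.assert_allclose(wave.paw, expected, rtol=1e-12)
    assert wave.paw[-1] == pytest.approx(26.3141, abs=5e-4)


def test_analytic_pc2_value(nominal):
    """pC2 after 1 s of 500 mL/s equals 10·(1 − e^(−0.625)) cmH2O."""
    wave = v.simulate_vem_piecewise_analytic(nominal, [(1.0, 500.0), (1 / FS, 0.0)], FS)
    # sample at exactly t = 1 s is the first pause sample: paw = pC1 + pC2
    paw_1s = wave.paw[int(FS)]
    pc1 = 500.0 * 1.0 / nominal.C1
    pc2_expected = 10.0 * (1 - np.exp(-0.625))
    assert paw_1s - pc1 == pytest.approx(pc2_expected, rel=1e-9)


@pytest.mark.parametrize(
    "segments",
    [
        [(1.0, 500.0), (4.0, 0.0)],
        [(0.48, 300.0), (0.32, 600.0), (2.0, 0.0)],
        [(2.0, 250.0)],
    ],
)
def test_numeric_matches_analytic_oracle(random_params, segments):
    """Exact ZOH discretisation equals the closed-form piecewise solution."""
    for p in random_params:
        ana = v.simulate_vem_piecewise_analytic(p, segments, FS)
        num = v.simulate_vem(p, ana.flow, FS)
        scale = np.max(np.abs(ana.paw))
        np.testing.assert_allclose(num.paw, ana.paw, atol=1e-6 * scale, rtol=0)


def test_zero_input_zero_state_response(nominal):
    flow = np.zeros(100)
    wave = v.simulate_vem(nominal, flow, FS)
    assert np.all(wave.paw == 0)
    ana = v.simulate_vem_piecewise_analytic(nominal, [(0.4, 0.0)], FS)
    assert np.all(ana.paw == 0)


def test_vcv_response_shape(nominal, vcv_wave):
    """Pressure rises during inspiration, then relaxes toward pC1 = V/C1 in the pause."""
    n_insp = int(FS)
    insp = vcv_wave.paw[:n_insp]
    assert np.all(np.diff(insp) > 0)
    eip = vcv_wave.paw[n_insp:]
    assert np.all(np.diff(eip) < 0)
    plateau = 500.0 * 1.0 / nominal.C1
    assert eip[-1] > plateau
    assert eip[-1] - plateau < eip[0] - plateau


def test_eip_decay_time_constant(nominal):
    """During the pause, paw − pC1 decays with time constant exactly R2·C2."""
    wave, states = v.simulate_vem(
        nominal, v.vcv_flow_profile(500, 1, 4, FS), FS, return_states=True
    )
    eip = slice(int(FS) + 1, None)
    excess = wave.paw[eip] - states[eip, 0]
    ratios = excess[1:] / excess[:-1]
    np.testing.assert_allclose(ratios, np.exp(-1 / (FS * nominal.tau_ve)), rtol=1e-9)


def test_state_conservation(random_params):
    """pC1·C1 tracks the delivered volume at every sample."""
    flow = v.vcv_flow_profile(500, 1, 4, FS)
    for p in random_params:
        wave, states = v.simulate_vem(p, flow, FS, return_states=True)
        vol_zoh = np.concatenate(([0.0], np.cumsum(flow[:-1]) / FS))
        np.testing.assert_allclose(states[:, 0] * p.C1, vol_zoh, atol=1e-9)
        # trapezoid volume agrees except the O(dt) ambiguity at the flow cut-off
        assert np.max(np.abs(states[:, 0] * p.C1 - wave.volume())) <= 500.0 / FS


@given(scale=st.floats(0.1, 10.0))
def test_linearity(scale):
    """Scaling the flow input scales the pressure response (zero initial state)."""
    p = v.NOMINAL_PARAMS
    rng = np.random.default_rng(0)
    flow = rng.normal(0, 200, 300)
    base = v.simulate_vem(p, flow, FS).paw
    scaled = v.simulate_vem(p, scale * flow, FS).paw
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-9)


def test_superposition(nominal):
    rng = np.random.default_rng(1)
    f1, f2 = rng.normal(0, 200, (2, 400))
    r1 = v.simulate_vem(nominal, f1, FS).paw
    r2 = v.simulate_vem(nominal, f2, FS).paw
    r12 = v.simulate_vem(nominal, f1 + f2, FS).paw
    np.testing.assert_allclose(r12, r1 + r2, rtol=1e-9, atol=1e-9)


def test_initial_state_offset(nominal):
    """A nonzero initial pC1 (PEEP-like baseline) shifts the response accordingly."""
    flow = np.zeros(50)
    wave = v.simulate_vem(nominal, flow, FS, initial_state=v.SimulationState(pC1=5.0))
    np.testing.assert_allclose(wave.paw, 5.0)


def test_fom_constant_flow_linear():
    p = v.FOMParams(R=0.010, C=30.0)
    flow = np.full(200, 500.0)
    wave = v.simulate_fom(p, flow, FS)
    np.testing.assert_allclose(wave.paw, 5.0 + 500.0 * wave.t / 30.0, rtol=1e-12)
    assert np.all(v.simulate_fom(p, np.zeros(10), FS).paw == 0)


def test_fom_is_vem_limit():
    """VEM degenerates to the FOM as R2 → 0 with C2 → ∞ (pC2 ≡ 0)."""
    flow = np.full(300, 400.0)
    fom = v.simulate_fom(v.FOMParams(R=0.010, C=30.0), flow, FS)
    vem = v.simulate_vem(v.VEMParams(R1=0.010, C1=30.0, R2=1e-9, C2=1e9), flow, FS)
    np.testing.assert_allclose(vem.paw, fom.paw, rtol=1e-6)


@pytest.mark.parametrize(
    "params",
    [
        v.VEMParams(0.01, 0.0, 0.02, 80.0),
        v.VEMParams(0.01, 30.0, 0.0, 80.0),
        v.VEMParams(0.01, 30.0, 0.02, 0.0),
    ],
)
def test_degenerate_model_error(params):
    with pytest.raises(v.DegenerateModelError):
        v.simulate_vem(params, np.zeros(10), FS)
    with pytest.raises(v.DegenerateModelError):
        v.simulate_vem_piecewise_analytic(params, [(1.0, 0.0)], FS)
    with pytest.raises(v.DegenerateModelError):
        v.simulate_fom(v.FOMParams(R=0.01, C=0.0), np.zeros(10), FS)


def test_waveform_validation():
    t = np.arange(10) / FS
    with pytest.raises(v.NonUniformSamplingError):
        v.Waveform(t**1.5 + t, np.zeros(10), np.zeros(10), FS)
    with pytest.raises(ValueError):
        v.Waveform(t, np.zeros(9), np.zeros(10), FS)
    with pytest.raises(ValueError):
        v.Waveform(t[:1], np.zeros(1), np.zeros(1), FS)
    with pytest.raises(ValueError):
        v.VEMParams(np.nan, 30.0, 0.02, 80.0)


def test_sse_basic():
    a = np.arange(5.0)
    assert v.sse(a, a) == 0.0
    assert v.sse(a, a + 2.0) == pytest.approx(5 * 4.0)
    perm = np.array([3, 1, 4, 0, 2])
    assert v.sse(a[perm], (a + 1.0)[perm]) == v.sse(a, a + 1.0)
    with pytest.raises(ValueError):
        v.sse(a, a[:3])
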