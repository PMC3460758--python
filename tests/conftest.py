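import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vemid as v

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 125.0


@pytest.fixture(scope="session")
def nominal():
    return v.NOMINAL_PARAMS


@pytest.fixture(scope="session")
def vcv_wave(nominal):
    """Noise-free nominal-parameter VCV response (500 mL/s x 1 s + 4 s pause, 125 Hz)."""
    flow = v.vcv_flow_profile(500.0, 1.0, 4.0, FS)
    return v.simulate_vem(nominal, flow, FS)


@pytest.fixture(scope="session")
def disturbance_wave(nominal):
    """Occluded inflation with a localized pressure artifact after the cut-off.

    An un-modelled +6 cmH2O disturbance over ~0.13 s right after the
    occlusion corrupts the integral regression enough that the one-shot
    Integral Method lands on non-physiological parameters, which the
    iterative method then corrects.
    """
    ds = v.scass_like_waveform(
        nominal, occlusion_volume=250.0, insp_flow=500.0, fs=FS, occlusion_s=0.5
    )
    paw = ds.clean_paw.copy()
    paw[65:81] += 6.0
    return ds.waveform.with_paw(paw)


@pytest.fixture(scope="session")
def random_params():
    """A handful of physiological parameter sets spread over the 0.5-1.5x range."""
    rng = np.random.default_rng(7)
    nominal = v.NOMINAL_PARAMS.as_array()
    return [
        v.VEMParams.from_array(rng.uniform(0.5, 1.5, 4) * nominal) for _ in range(5)
    ]
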