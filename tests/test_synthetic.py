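"""Synthetic VCV data generation: flow profiles, parameter draws, noise, corpus."""

import numpy as np
import pytest

import vemid as v

FS = 125.0


class TestVCVProfile:
    def test_study_profile_counts(self):
        flow = v.vcv_flow_profile(500, 1, 4, 125)
        assert flow.size == 625
        assert np.all(flow[:125] == 500.0)
        assert np.all(flow[125:] == 0.0)

    def test_delivered_volume_independent_of_fs(self):
        for fs in (50.0, 125.0, 500.0):
            flow = v.vcv_flow_profile(420.0, 0.8, 2.0, fs)
            assert np.sum(flow) / fs == pytest.approx(420.0 * 0.8)

    def test_sampling_rate_invariance_of_response(self, nominal):
        """The analytic pressure response is the same signal at shared timestamps."""
        lo = v.simulate_vem(nominal, v.vcv_flow_profile(500, 1, 4, 125), 125.0)
        hi = v.simulate_vem(nominal, v.vcv_flow_profile(500, 1, 4, 250), 250.0)
        np.testing.assert_allclose(hi.paw[::2], lo.paw, rtol=1e-12)

    def test_invalid_durations(self):
        with pytest.raises(ValueError):
            v.vcv_flow_profile(500, 0, 4, 125)
        with pytest.raises(ValueError):
            v.vcv_flow_profile(500, 1, -1, 125)


class TestParameterDraws:
    def test_bounds(self, nominal):
        cfg = v.MonteCarloConfig(n_param_sets=200, seed=3)
        draws = np.array([p.as_array() for p in v.draw_parameter_sets(cfg)])
        lo = 0.5 * nominal.as_array()
        hi = 1.5 * nominal.as_array()
        assert np.all(draws >= lo) and np.all(draws <= hi)
        # each parameter actually spans most of its range
        assert np.all(np.ptp(draws, axis=0) > 0.8 * (hi - lo))

    def test_degenerate_range_returns_nominal(self, nominal):
        cfg = v.MonteCarloConfig(n_param_sets=3, range_lo=1.0, range_hi=1.0, seed=0)
        for p in v.draw_parameter_sets(cfg):
            np.testing.assert_array_equal(p.as_array(), nominal.as_array())

    def test_seed_determinism(self):
        cfg = v.MonteCarloConfig(n_param_sets=10, seed=11)
        a = v.draw_parameter_sets(cfg)
        b = v.draw_parameter_sets(cfg)
        assert a == b


class TestNoise:
    def test_zero_fraction_is_identity(self):
        paw = np.linspace(0, 20, 50)
        np.testing.assert_array_equal(v.add_noise(paw, 0.0, 1), paw)

    def test_zero_signal_stays_zero(self):
        assert np.all(v.add_noise(np.zeros(100), 0.05, 1) == 0)

    def test_noise_sd_tracks_sample_magnitude(self):
        """5% noise on a 20 cmH2O sample has SD ≈ 1 cmH2O."""
        paw = np.full(20_000, 20.0)
        noisy = v.add_noise(paw, 0.05, 42)
        assert np.std(noisy - paw) == pytest.approx(1.0, rel=0.05)
        assert np.mean(noisy - paw) == pytest.approx(0.0, abs=0.05)

    def test_uniform_noise_bounded(self):
        paw = np.full(10_000, 20.0)
        dev = v.add_noise(paw, 0.05, 7, distribution="uniform") - paw
        assert np.max(np.abs(dev)) <= 1.0 + 1e-12
        assert np.std(dev) == pytest.approx(1.0 / np.sqrt(3), rel=0.05)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            v.add_noise(np.ones(5), -0.1, 1)


class TestMonteCarloCorpus:
    def test_counts_and_ids(self):
        cfg = v.MonteCarloConfig(n_param_sets=5, n_noise_sets=3, seed=2)
        corpus = v.generate_monte_carlo(cfg)
        assert len(corpus) == 5 * (3 + 1)
        assert sum(ds.noise_set_id == 0 for ds in corpus) == 5
        clean = [ds for ds in corpus if ds.noise_set_id == 0]
        for ds in clean:
            np.testing.assert_array_equal(ds.waveform.paw, ds.clean_paw)

    def test_clean_roundtrip_bit_for_bit(self):
        cfg = v.MonteCarloConfig(n_param_sets=3, n_noise_sets=1, seed=5)
        for ds in v.generate_monte_carlo(cfg):
            resim = v.simulate_vem(ds.true_params, ds.waveform.flow, ds.waveform.fs)
            np.testing.assert_array_equal(resim.paw, ds.clean_paw)

    def test_corpus_pure_function_of_config(self):
        cfg = v.MonteCarloConfig(n_param_sets=4, n_noise_sets=2, seed=9)
        a = v.generate_monte_carlo(cfg)
        b = v.generate_monte_carlo(cfg)
        for da, db in zip(a, b):
            assert da.true_params == db.true_params
            np.testing.assert_array_equal(da.waveform.paw, db.waveform.paw)

    def test_no_noise_sets_gives_clean_only(self):
        cfg = v.MonteCarloConfig(n_param_sets=2, n_noise_sets=0, seed=1)
        corpus = v.generate_monte_carlo(cfg)
        assert len(corpus) == 2 and all(ds.noise_set_id == 0 for ds in corpus)

    def test_empirical_noise_level(self):
        """Relative noise over the corpus matches the configured fraction."""
        cfg = v.MonteCarloConfig(n_param_sets=10, n_noise_sets=5, seed=8)
        ratios = []
        for ds in v.generate_monte_carlo(cfg):
            if ds.noise_set_id == 0:
                continue
            dev = ds.waveform.paw - ds.clean_paw
            keep = np.abs(ds.clean_paw) > 1e-9
            ratios.append(np.std(dev[keep] / np.abs(ds.clean_paw[keep])))
        assert np.mean(ratios) == pytest.approx(0.05, rel=0.05)


class TestScassWaveform:
    # 240 mL at 500 mL/s = 0.48 s = 60 whole samples at 125 Hz
    def test_occlusion_onset_time(self, nominal):
        ds = v.scass_like_waveform(nominal, 240.0, 500.0, FS, 4.0)
        n_insp = int(np.argmax(ds.waveform.flow == 0))
        assert n_insp / FS == pytest.approx(0.48)
        assert np.sum(ds.waveform.flow) / FS == pytest.approx(240.0)

    def test_occlusion_decay_time_constant(self, nominal):
        ds = v.scass_like_waveform(nominal, 240.0, 500.0, FS, 4.0)
        pc1 = 240.0 / nominal.C1
        occ = slice(int(0.48 * FS) + 1, None)
        excess = ds.waveform.paw[occ] - pc1
        ratios = excess[1:] / excess[:-1]
        np.testing.assert_allclose(ratios, np.exp(-1 / (FS * nominal.tau_ve)), rtol=1e-9)

    def test_long_occlusion_plateau(self, nominal):
        ds = v.scass_like_waveform(nominal, 240.0, 500.0, FS, 30.0)
        assert ds.waveform.paw[-1] == pytest.approx(240.0 / nominal.C1, rel=1e-6)

    def test_unreachable_volume(self, nominal):
        with pytest.raises(ValueError):
            v.scass_like_waveform(nominal, 5000.0, 500.0, FS, 1.0, max_inspiration_s=2.0)
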