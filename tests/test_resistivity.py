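"""Spectrogram analysis, first-moment velocity and resistivity recovery."""

import numpy as np
import pytest

import ufd_hemo as u
from ufd_hemo.resistivity import SpectrogramSpec, VelocityTrace
from conftest import bare_field

F0 = 6.4e6
C = 1540.0


class TestSpectrogram:
    def test_pure_tone_peaks_at_doppler_bin(self):
        fs, fd = 2000.0, 500.0
        t = np.arange(256) / fs
        x = np.exp(2j * np.pi * fd * t)
        spec = SpectrogramSpec()
        times, freqs, p = u.pixel_spectrogram(x, spec, fs)
        bin_width = fs / spec.n_fft
        for k in range(p.shape[-2]):
            assert abs(freqs[np.argmax(p[k])] - fd) <= bin_width

    def test_zero_signal_gives_zero_spectrogram(self):
        _, _, p = u.pixel_spectrogram(np.zeros(128, complex),
                                      SpectrogramSpec(), 2000.0)
        np.testing.assert_array_equal(p, 0.0)

    def test_parseval_per_slice(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        spec = SpectrogramSpec()
        _, _, p = u.pixel_spectrogram(x, spec, 2000.0)
        win = spec.window()
        hop = spec.hop
        for k in range(p.shape[-2]):
            seg = x[k * hop:k * hop + spec.window_length] * win
            expected = spec.n_fft * np.sum(np.abs(seg) ** 2)
            assert np.sum(p[k]) == pytest.approx(expected, rel=1e-10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            u.pixel_spectrogram(np.zeros(10, complex), SpectrogramSpec(),
                                2000.0)

    @pytest.mark.parametrize("kwargs", [
        dict(window_length=64, overlap=64),
        dict(window_length=64, overlap=-1),
        dict(window_length=64, overlap=0, zero_pad=0),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpectrogramSpec(**kwargs)


class TestMeanVelocity:
    def delta(self, f_hz, nfft=64, fs=4000.0):
        # fs chosen so the requested frequencies fall exactly on DFT bins
        freqs = np.fft.fftshift(np.fft.fftfreq(nfft, 1 / fs))
        p = np.zeros(nfft)
        p[np.argmin(np.abs(freqs - f_hz))] = 1.0
        return p, freqs

    def test_delta_at_1khz(self):
        p, freqs = self.delta(1000.0)
        v = u.mean_velocity(p, freqs, F0, C, noise_floor=None)
        assert v == pytest.approx(1000.0 * C / (2 * F0), rel=1e-3)
        assert v == pytest.approx(0.1203, abs=2e-4)

    def test_delta_at_zero_gives_zero(self):
        p, freqs = self.delta(0.0)
        assert u.mean_velocity(p, freqs, F0, C, noise_floor=None) == 0.0

    def test_first_moment_linearity(self):
        p1, freqs = self.delta(500.0)
        p2, _ = self.delta(1500.0)
        v_two = u.mean_velocity(p1 + p2, freqs, F0, C, noise_floor=None)
        p3, _ = self.delta(1000.0)
        v_one = u.mean_velocity(p3, freqs, F0, C, noise_floor=None)
        assert v_two == pytest.approx(v_one, rel=1e-6)

    def test_all_zero_slice_flagged_invalid(self):
        freqs = np.fft.fftshift(np.fft.fftfreq(64, 1 / 4000.0))
        assert np.isnan(u.mean_velocity(np.zeros(64), freqs, F0, C))

    def test_constant_velocity_bias_below_half_bin(self, small_config):
        v_true = 0.07
        pix = np.arange(50)
        f = bare_field((32, 32), vessel_pixels=pix, counts=20, v=v_true,
                       jitter=0.0, noise_sd=0.05)
        block = u.simulate_iq_block(f, small_config, seed=3,
                                    dtype=np.complex128)
        spec = SpectrogramSpec()
        sel = block.data.reshape(-1, block.n_frames)[pix]
        _, freqs, p = u.pixel_spectrogram(sel, spec, block.frame_rate)
        v = u.mean_velocity(p, freqs, F0, C)
        half_bin_speed = 0.5 * (block.frame_rate / spec.n_fft) * C / (2 * F0)
        assert abs(np.nanmedian(v) - v_true) < half_bin_speed


class TestResistivityIndex:
    def make_trace(self, speeds):
        speeds = np.asarray(speeds, float)
        return VelocityTrace(times=np.arange(speeds.size) * 0.01,
                             speed=speeds, valid=np.ones(speeds.size, bool))

    def test_formula(self):
        tr = self.make_trace(np.linspace(0.04, 0.10, 30))
        assert u.resistivity_index(tr) == pytest.approx(0.6)

    def test_constant_velocity_gives_zero(self):
        assert u.resistivity_index(self.make_trace(np.full(20, 0.05))) == 0.0

    def test_zero_diastolic_gives_one(self):
        tr = self.make_trace(np.concatenate([[0.0], np.linspace(0.01, 0.1,
                                                                19)]))
        assert u.resistivity_index(tr) == pytest.approx(1.0)

    def test_scaling_invariance(self):
        v = np.abs(np.sin(np.linspace(0, 3, 40))) + 0.01
        a = u.resistivity_index(self.make_trace(v))
        b = u.resistivity_index(self.make_trace(3.7 * v))
        assert a == pytest.approx(b, rel=1e-12)

    def test_subcycle_trace_invalid(self):
        tr = self.make_trace(np.linspace(0.04, 0.1, 10))  # 0.09 s
        with pytest.warns(UserWarning, match="cardiac"):
            assert np.isnan(u.resistivity_index(tr, heart_rate=4.2))


@pytest.fixture(scope="module")
def ri_config():
    # 600 frames (0.3 s) covers one cardiac cycle at 4.2 Hz
    return u.AcquisitionConfig.desk_scale(frames_per_block=600,
                                          grid_shape=(24, 24))


def prescribed_ri_block(ri, config, seed, v_sys=0.10):
    pix = np.arange(150)
    f = bare_field(config.grid_shape, vessel_pixels=pix, counts=25,
                   v_sys=v_sys, v_dia=v_sys * (1 - ri), jitter=0.02,
                   noise_sd=0.05)
    return pix, u.simulate_iq_block(f, config, seed=seed,
                                    dtype=np.complex128)


class TestResistivityMap:
    def test_prescribed_ri_recovered(self, ri_config):
        errors = []
        for ri in (0.2, 0.5, 0.8):
            pix, block = prescribed_ri_block(ri, ri_config, seed=11)
            mask = np.zeros(ri_config.grid_shape, bool)
            mask.ravel()[pix] = True
            rmap = u.resistivity_map(block, mask=mask, config=ri_config,
                                     heart_rate=4.2)
            vals = rmap.values[np.isfinite(rmap.values)]
            errors.append(abs(np.median(vals) - ri))
        assert max(errors) < 0.05

    def test_constant_flow_gives_near_zero_ri(self, ri_config):
        pix, block = prescribed_ri_block(0.0, ri_config, seed=4)
        mask = np.zeros(ri_config.grid_shape, bool)
        mask.ravel()[pix] = True
        rmap = u.resistivity_map(block, mask=mask, config=ri_config)
        assert np.nanmedian(rmap.values) < 0.1

    def test_hyperemia_lowers_ri(self, ri_config, control_template):
        medians = {}
        for label, t in (("baseline", -20.0), ("peak", 10.0)):
            vs, vd = control_template.velocity_at(t)
            ri = 1 - vd / vs
            pix, block = prescribed_ri_block(ri, ri_config, seed=6,
                                             v_sys=vs)
            mask = np.zeros(ri_config.grid_shape, bool)
            mask.ravel()[pix] = True
            rmap = u.resistivity_map(block, mask=mask, config=ri_config)
            medians[label] = np.nanmedian(rmap.values)
        assert medians["peak"] < medians["baseline"]

    def test_values_in_unit_interval(self, ri_config):
        pix, block = prescribed_ri_block(0.5, ri_config, seed=9)
        rmap = u.resistivity_map(block, config=ri_config)
        vals = rmap.values[np.isfinite(rmap.values)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_block_shorter_than_cycle_rejected(self, small_config):
        pix, block = prescribed_ri_block(0.5, small_config, seed=0)
        with pytest.raises(ValueError, match="cardiac"):
            u.resistivity_map(block, config=small_config, heart_rate=4.2)
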