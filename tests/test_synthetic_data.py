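"""Simulator contracts: velocity waveform, IQ physics, templates, cohorts."""

import numpy as np
import pytest

import ufd_hemo as u
import ufd_hemo.synthetic_data as sd
from conftest import bare_field


class TestPulsatileVelocity:
    def test_peak_attained_at_systole(self):
        t = np.linspace(0, 1 / 4.2, 2001)
        v = u.pulsatile_velocity(t, 4.2, 0.10, 0.04)
        assert np.max(v) == pytest.approx(0.10, abs=1e-6)

    def test_degenerate_pulse_is_constant(self):
        t = np.linspace(0, 2.0, 500)
        v = u.pulsatile_velocity(t, 4.2, 0.05, 0.05)
        assert np.all(v == pytest.approx(0.05))

    def test_minimum_is_diastolic(self):
        t = np.linspace(0, 1 / 4.2, 4001)
        v = u.pulsatile_velocity(t, 4.2, 0.10, 0.04)
        assert np.min(v) == pytest.approx(0.04, abs=1e-6)

    def test_periodicity(self):
        t = np.linspace(0, 0.2, 300)
        hr = 3.7
        v1 = u.pulsatile_velocity(t, hr, 0.09, 0.03)
        v2 = u.pulsatile_velocity(t + 1 / hr, hr, 0.09, 0.03)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(heart_rate=-1, v_systolic=0.1, v_diastolic=0.05),
        dict(heart_rate=4, v_systolic=0.02, v_diastolic=0.05),
        dict(heart_rate=4, v_systolic=0.1, v_diastolic=-0.01),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            u.pulsatile_velocity(0.0, **kwargs)


class TestIQBlockSynthesis:
    def test_static_scatterer_gives_identical_frames_rank_one(self,
                                                              small_config):
        f = bare_field((32, 32), tissue_amp=0.0)
        f.tissue_amp[10, 12] = 5.0
        block = u.simulate_iq_block(f, small_config, seed=0,
                                    dtype=np.complex128)
        frames = block.data.reshape(-1, block.n_frames)
        np.testing.assert_allclose(
            frames, np.broadcast_to(frames[:, :1], frames.shape), atol=1e-12)
        s = u.singular_spectrum(block)
        # second singular value at the eigensolver's numerical floor
        assert s[1] < 1e-6 * s[0]

    def test_constant_velocity_phase_increment(self, small_config):
        v = 0.06
        f = bare_field((32, 32), vessel_pixels=[100], counts=10, v=v)
        block = u.simulate_iq_block(f, small_config, seed=1,
                                    dtype=np.complex128)
        pix = block.data.reshape(-1, block.n_frames)[100]
        expected = (4 * np.pi * small_config.center_frequency * v
                    / (small_config.sound_speed * small_config.frame_rate))
        incr = np.angle(pix[1:] * np.conj(pix[:-1]))
        np.testing.assert_allclose(incr, expected, atol=1e-5)

    def test_same_seed_is_bit_identical(self, small_config, control_template,
                                        layout64, regions64):
        lay = u.build_vessel_layout(u.default_region_set((32, 32)), seed=5)
        blocks = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            f = sd.field_for_time(control_template, lay, small_config, 10.0,
                                  None, rng)
            blocks.append(u.simulate_iq_block(f, small_config, seed=rng))
        assert blocks[0].data.tobytes() == blocks[1].data.tobytes()

    def test_doppler_frequency_matches_periodogram_peak(self, small_config):
        v = 0.08
        f = bare_field((32, 32), vessel_pixels=[64], counts=10, v=v)
        block = u.simulate_iq_block(f, small_config, seed=2,
                                    dtype=np.complex128)
        pix = block.data.reshape(-1, block.n_frames)[64]
        spec = np.abs(np.fft.fft(pix)) ** 2
        freqs = np.fft.fftfreq(block.n_frames, 1 / block.frame_rate)
        f_peak = freqs[np.argmax(spec)]
        f_true = (2 * small_config.center_frequency * v
                  / small_config.sound_speed)
        bin_width = block.frame_rate / block.n_frames
        assert abs(f_peak - f_true) <= bin_width

    def test_tissue_energy_dominates_blood_energy(self, small_config,
                                                  control_template):
        lay = u.build_vessel_layout(u.default_region_set((32, 32)), seed=3)
        rng = np.random.default_rng(4)
        f = sd.field_for_time(control_template, lay, small_config, -20.0,
                              None, rng)
        tissue_energy = float(np.sum(f.tissue_amp ** 2))
        blood_energy = float(np.sum(f.vessel_counts) * f.blood_amp ** 2)
        assert tissue_energy > 100 * blood_energy   # >= 20 dB margin

    def test_aliasing_flagged(self, small_config):
        f = bare_field((32, 32), vessel_pixels=[10], counts=5, v=0.20)
        with pytest.warns(UserWarning, match="unaliased"):
            block = u.simulate_iq_block(f, small_config, seed=0)
        assert block.aliased


class TestTemplates:
    def test_baseline_anchored_at_zero(self, control_template, tlv_template):
        for tpl in (control_template, tlv_template):
            t = np.linspace(-23, -13.01, 30)
            for region in tpl.region_values:
                np.testing.assert_allclose(tpl.relative_cbv(region, t), 0.0)

    def test_control_peaks(self, control_template):
        t = np.linspace(0, 40, 2000)
        whole = np.asarray(control_template.whole_slice_cbv(t))
        assert np.max(whole) == pytest.approx(150.0, abs=0.5)
        hippo = control_template.relative_cbv("hippocampus", t)
        assert np.max(hippo) == pytest.approx(210.0, abs=0.5)

    def test_peak_density_multiplier_is_2p5(self, control_template):
        mult = 1.0 + np.asarray(
            control_template.whole_slice_cbv(10.0)) / 100.0
        assert mult == pytest.approx(2.5, abs=0.01)

    def test_tlv_below_control_during_window(self, control_template,
                                             tlv_template):
        t = np.linspace(7, 37, 400)
        for region in control_template.region_values:
            c = np.asarray(control_template.relative_cbv(region, t))
            m = np.asarray(tlv_template.relative_cbv(region, t))
            assert np.all(m <= c + 1e-9)
        cw = np.asarray(control_template.whole_slice_cbv(t))
        mw = np.asarray(tlv_template.whole_slice_cbv(t))
        assert np.all(mw <= cw + 1e-9)

    def test_arrest_map_within_band_post_cpr(self, control_template,
                                             tlv_template):
        for tpl in (control_template, tlv_template):
            cohort = u.make_experiment(tpl, u.AcquisitionConfig.desk_scale(),
                                       n_subjects=3, seed=8, interval_s=60.0)
            for s in cohort:
                post = s.block_times_min >= tpl.map_clip_from
                assert np.all(s.map_values[post] >= 60.0 - 1e-9)
                assert np.all(s.map_values[post] <= 90.0 + 1e-9)

    def test_sham_sweep_covers_wide_map_range(self, sham_template):
        t = np.linspace(0, 10, 200)
        m = np.asarray(sham_template.map_at(t))
        assert m.min() < 50 and m.max() > 130
        cbv = np.asarray(sham_template.whole_slice_cbv(t))
        assert np.max(np.abs(cbv)) < 45.0   # plateau: moderate CBV response

    def test_resistivity_drops_at_control_peak(self, control_template):
        vs_base, vd_base = control_template.velocity_at(-20.0)
        vs_peak, vd_peak = control_template.velocity_at(10.0)
        ri = lambda vs, vd: (vs - vd) / vs
        assert ri(vs_peak, vd_peak) < ri(vs_base, vd_base)


class TestMakeExperiment:
    def test_sham_block_cadence(self, sham_template):
        cfg = u.AcquisitionConfig.desk_scale(grid_shape=(32, 32))
        series = u.make_experiment(sham_template, cfg, n_subjects=1, seed=0)
        # 10-minute session imaged every 6 s
        assert series[0].n_blocks == 101
        dt = np.diff(series[0].block_times_min) * 60.0
        np.testing.assert_allclose(dt, 6.0)

    def test_density_tracks_template(self, control_template, small_config):
        lay = u.build_vessel_layout(u.default_region_set((32, 32)), seed=6)
        rng = np.random.default_rng(0)
        f_base = sd.field_for_time(control_template, lay, small_config,
                                   -20.0, None, rng)
        f_peak = sd.field_for_time(control_template, lay, small_config,
                                   10.0, None, rng)
        ratio = f_peak.vessel_counts.sum() / f_base.vessel_counts.sum()
        assert ratio == pytest.approx(2.5, abs=0.05)

    def test_subject_factors_average_to_template(self, control_template):
        rng = np.random.default_rng(123)
        f = [control_template.draw_subject_factors(rng)["hippocampus"]
             for _ in range(4000)]
        assert np.mean(f) == pytest.approx(1.0, abs=0.02)

    def test_artifact_window_marked(self, control_template):
        cfg = u.AcquisitionConfig.desk_scale(grid_shape=(32, 32))
        s = u.make_experiment(control_template, cfg, n_subjects=1, seed=0,
                              interval_s=60.0)[0]
        inside = (s.block_times_min >= 23) & (s.block_times_min <= 26)
        assert s.artifact[inside].all() and not s.artifact[~inside].any()

    def test_experiment_is_deterministic(self, control_template):
        cfg = u.AcquisitionConfig.desk_scale(frames_per_block=50,
                                             grid_shape=(16, 16))
        b = [u.make_experiment(control_template, cfg, n_subjects=1, seed=77,
                               interval_s=600.0)[0].block(3)
             for _ in range(2)]
        assert b[0].data.tobytes() == b[1].data.tobytes()

    def test_n_subjects_validated(self, control_template, small_config):
        with pytest.raises(ValueError):
            u.make_experiment(control_template, small_config, n_subjects=0)


class TestRegionSeriesFastPath:
    def test_ground_truth_recovered_without_noise(self, control_template):
        subjects = u.simulate_region_series(control_template, n_subjects=3,
                                            seed=1, interval_s=60.0,
                                            noise_sd=0.0)
        for sub in subjects:
            s = sub.series["hippocampus"]
            truth = control_template.relative_cbv("hippocampus", s.times,
                                                  sub.factors)
            np.testing.assert_allclose(s.values, truth, atol=1e-9)

    def test_cloud_excludes_artifact_points(self, control_template):
        sub = u.simulate_region_series(control_template, n_subjects=1,
                                       seed=2, interval_s=30.0)[0]
        cbv, mp = sub.cloud_samples(window=(7.0, 37.0))
        n_window = np.sum((sub.map_times >= 7) & (sub.map_times <= 37))
        n_artifact = np.sum((sub.map_times >= 23) & (sub.map_times <= 26))
        assert cbv.size == n_window - n_artifact
        assert mp.size == cbv.size
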