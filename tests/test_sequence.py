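"""Bloch simulation of the tagged bSSFP sequence."""

import numpy as np
import pytest

from rttag.fourier import fft2c, ifft2c
from rttag.phantom import PhantomConfig, TissueMap, build_phantom, render_object
from rttag.sampling import full_sampling_plan, make_sampling_plan
from rttag.sequence import (MagnetizationGrid, SequenceProtocol,
                            acquire_series, apply_fat_saturation,
                            apply_spamm_prep, run_ramp_up,
                            steady_state_signal, timing_summary)
from rttag.strain import tag_minima_spacing


def equilibrium_1d(n=640, t1=1400.0, t2=45.0):
    return MagnetizationGrid.equilibrium(np.ones(n), t1, t2)


class TestFatSaturation:
    def test_water_untouched_fat_inverted(self):
        prot = SequenceProtocol()
        mag = MagnetizationGrid.equilibrium(np.ones(2), 1400.0, 45.0)
        mag.df = np.array([0.0, prot.fat_shift_hz])
        apply_fat_saturation(mag, prot)
        assert mag.mz[0] == pytest.approx(1.0)
        assert mag.mz[1] == pytest.approx(np.cos(np.deg2rad(110.0)), abs=1e-12)
        assert np.all(mag.mxy == 0)  # spoiled

    def test_disabled_is_identity(self):
        prot = SequenceProtocol(fatsat_enabled=False)
        mag = equilibrium_1d(4)
        mz0 = mag.mz.copy()
        apply_fat_saturation(mag, prot)
        assert np.array_equal(mag.mz, mz0)


class TestSpammPrep:
    def test_zero_total_flip_is_identity(self):
        prot = SequenceProtocol(spamm_total_flip=0.0)
        mag = equilibrium_1d()
        apply_spamm_prep(mag, prot, np.arange(640) * 0.1)
        assert np.allclose(mag.mz, 1.0)

    def test_tag_minima_spacing_matches_protocol(self):
        # 0.1 mm isochromat spacing over 64 mm; default 8 mm tag spacing
        prot = SequenceProtocol()
        x = np.arange(0, 64, 0.1)
        mag = equilibrium_1d(len(x))
        apply_spamm_prep(mag, prot, x)
        spacing = tag_minima_spacing(mag.mz, 0.1)
        assert spacing == pytest.approx(8.0, abs=0.1)

    def test_dc_term_matches_rotation_product_oracle(self):
        # independent oracle: explicit 3x3 rotation-matrix product per phase
        prot = SequenceProtocol()
        phases = np.linspace(0, 2 * np.pi, 64, endpoint=False)

        def rot_x(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[1, 0, 0], [0, c, s], [0, -s, c]])

        def rot_z(p):
            c, s = np.cos(p), np.sin(p)
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

        w = np.array(prot.spamm_weights, float)
        flips = np.deg2rad(prot.spamm_total_flip * w / w.sum())
        expected = []
        for ph in phases:
            m = np.array([0.0, 0.0, 1.0])
            for i, a in enumerate(flips):
                m = rot_x(a) @ m
                if i < len(flips) - 1:
                    m = rot_z(ph) @ m
            expected.append(m[2])
        oracle_dc = np.mean(expected)

        x = phases / (2 * np.pi) * prot.d_tag
        mag = equilibrium_1d(len(x))
        apply_spamm_prep(mag, prot, x)
        assert np.mean(mag.mz) == pytest.approx(oracle_dc, abs=1e-6)

    def test_invalid_tag_spacing_raises(self):
        with pytest.raises(ValueError):
            SequenceProtocol(d_tag=-1.0)


class TestRampUpAndSteadyState:
    def test_zero_pulses_identity(self):
        prot = SequenceProtocol(n_ramp=0)
        mag = equilibrium_1d(4)
        run_ramp_up(mag, prot)
        assert np.allclose(mag.mz, 1.0) and mag.time_ms == 0.0

    def test_elapsed_time_five_pulses(self):
        prot = SequenceProtocol()
        mag = equilibrium_1d(4)
        run_ramp_up(mag, prot)
        assert mag.time_ms == pytest.approx(5 * 2.62)

    def test_long_run_reaches_closed_form(self):
        prot = SequenceProtocol()
        mag = equilibrium_1d(1)
        run_ramp_up(mag, prot)
        last = None
        for _ in range(2000):
            phase = 180.0 * (mag.pulse_parity % 2)
            mag.rotate(prot.flip_deg, phase)
            mag.pulse_parity += 1
            last = abs(mag.mxy[0])
            mag.relax(prot.tr)
        ss = steady_state_signal(1400.0, 45.0, prot.tr, prot.flip_deg)
        assert abs(last - ss) / ss < 1e-3

    def test_steady_state_zero_flip(self):
        assert steady_state_signal(1400.0, 45.0, 2.62, 1e-12) < 1e-10

    def test_steady_state_long_t1_t2_limit_vs_iteration(self):
        with pytest.raises(ValueError):
            steady_state_signal(45.0, 1400.0, 2.62, 30.0)  # T1 < T2
        # relaxation-free limit: the after-pulse signal alternates between
        # sin(alpha) and 0 under +/- alternation, whose two-pulse average is
        # the closed-form limit sin(alpha)/(1+E) -> sin(alpha)/2
        val = steady_state_signal(1e9, 1e9 - 1, 2.62, 30.0)
        mag = MagnetizationGrid.equilibrium(np.ones(1), 1e9, 1e9 - 1)
        sigs = []
        for i in range(10000):
            mag.rotate(30.0, 180.0 * (i % 2))
            sigs.append(abs(mag.mxy[0]))
            mag.relax(2.62)
        assert np.mean(sigs[-2:]) == pytest.approx(val, rel=1e-6)

    def test_myocardium_defaults_match_brute_force_iteration(self):
        prot = SequenceProtocol()
        val = steady_state_signal(1400.0, 45.0, prot.tr, prot.flip_deg)
        mag = MagnetizationGrid.equilibrium(np.ones(1), 1400.0, 45.0)
        for i in range(20000):
            mag.rotate(prot.flip_deg, 180.0 * (i % 2))
            sig = abs(mag.mxy[0])
            mag.relax(prot.tr)
        assert sig == pytest.approx(val, rel=1e-3)

    def test_magnitude_never_exceeds_m0(self):
        prot = SequenceProtocol()
        mag = equilibrium_1d(64)
        apply_spamm_prep(mag, prot, np.arange(64) * 0.5)
        run_ramp_up(mag, prot)
        for i in range(50):
            mag.rotate(prot.flip_deg, 180.0 * (i % 2))
            norm = np.sqrt(np.abs(mag.mxy) ** 2 + mag.mz**2)
            assert (norm <= mag.m0 + 1e-9).all()
            mag.relax(prot.tr)


class TestTiming:
    def test_trigger_delay_budget(self):
        t = timing_summary(SequenceProtocol())
        assert t.trigger_delay_ms == pytest.approx(38.0, abs=1e-9)
        assert t.fatsat_ms == 5.1 and t.rampup_ms == pytest.approx(13.1)

    def test_temporal_resolution_and_frames(self):
        prot = SequenceProtocol()
        t = timing_summary(prot)
        assert t.temporal_resolution_ms == pytest.approx(28.82)
        assert t.frames_per_window == 69
        assert timing_summary(SequenceProtocol(window_ms=1200.0)).frames_per_window == 41


class TestAcquireSeries:
    N = 64

    def _uniform_static(self):
        # single-tissue static disk so transverse magnetization is
        # proportional to proton density
        cfg = PhantomConfig(matrix=self.N, pixel_spacing=2.0, gcs_peak=0.0)
        tissue, motion = build_phantom(cfg)
        tissue.t1[:] = 1400.0
        tissue.t2[:] = 45.0
        tissue.pd = (tissue.pd > 0).astype(float)
        return tissue, motion

    def test_full_sampling_untagged_static_inverse_is_object(self):
        tissue, motion = self._uniform_static()
        prot = SequenceProtocol(matrix=self.N, fov=self.N * 2.0,
                                window_ms=400.0, spamm_total_flip=0.0)
        plan = full_sampling_plan(self.N, 3)
        ks = acquire_series(tissue, motion, prot, plan, snapshot=True)
        img = np.abs(ifft2c(ks.data[-1]))
        obj = np.abs(render_object(tissue, motion, 0.0).data)
        scale = (img * obj).sum() / (obj * obj).sum()
        rms = np.sqrt(np.mean((img - scale * obj) ** 2)) / (scale * obj).max()
        assert rms < 0.02

    def test_tag_harmonic_fades_monotonically(self):
        tissue, motion = self._uniform_static()
        prot = SequenceProtocol(matrix=self.N, fov=self.N * 2.0, window_ms=600.0)
        frames = timing_summary(prot).frames_per_window
        plan = full_sampling_plan(self.N, frames)
        ks = acquire_series(tissue, motion, prot, plan, snapshot=True)
        freqs = np.fft.fftshift(np.fft.fftfreq(self.N, d=2.0))
        band = np.abs(freqs - 1.0 / prot.d_tag) < 0.04
        amp = np.abs(ks.data[:, :, band]).max(axis=(1, 2))
        # non-increasing, allowing one transient violation while the bSSFP
        # approach to steady state rings
        violations = (np.diff(amp) > 1e-9).sum()
        assert violations <= 1
        assert amp[-1] < amp[0]

    def test_line_times_increase_within_frame(self, desk_phantom, desk_protocols):
        _, tissue, motion = desk_phantom
        prot_x, _ = desk_protocols
        plan = make_sampling_plan(96, 2, 6, 3, seed=1)
        ks = acquire_series(tissue, motion, prot_x, plan)
        for f in range(3):
            t = ks.line_times[f][np.isfinite(ks.line_times[f])]
            assert (np.diff(t) > 0).all()
        # unsampled entries exactly zero
        unsampled = ~ks.mask[0]
        assert np.all(ks.data[0][unsampled, :] == 0)

    def test_plan_protocol_mismatch_raises(self, desk_phantom, desk_protocols):
        _, tissue, motion = desk_phantom
        prot_x, _ = desk_protocols
        with pytest.raises(ValueError):
            acquire_series(tissue, motion, prot_x,
                           make_sampling_plan(128, 2, 6, 2, seed=0))
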