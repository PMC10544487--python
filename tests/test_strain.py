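"""Harmonic-phase extraction, tracking and mid-wall strain."""

import numpy as np
import pytest

from rttag.coils import make_coil_sensitivities
from rttag.fourier import fft2c, ifft2c
from rttag.phantom import PhantomConfig, build_phantom, deform_point
from rttag.recon import ImageSeries, cs_recon, zero_pad_enhance
from rttag.sampling import make_sampling_plan
from rttag.sequence import SequenceProtocol, acquire_series, timing_summary
from rttag.strain import (MaterialTrajectory, circle_contour,
                          extract_harmonic_phase, harp_track, measure_gcs,
                          midwall_gcs, summarize_gcs)

from conftest import DESK_N

D_TAG = 8.0


def synthetic_tagged_series(n=96, frames=3, d_tag=D_TAG, dx=2.0,
                            shift_mm=(0.0, 0.0)):
    """Annulus magnitude image with a cosine tag along x; optional rigid
    shift applied analytically in k-space (exact sub-pixel translation)."""
    ax = (np.arange(n) - n / 2) * dx
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(yy, xx)
    body = np.clip((35.0 - r) / 4, 0, 1) * np.clip((r - 12.0) / 4 + 1, 0, 1)
    img = body * (1.0 + 0.6 * np.cos(2 * np.pi * xx / d_tag))
    k = fft2c(img)
    fy = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    data = []
    for f in range(frames):
        sy, sx = (shift_mm[0] * f, shift_mm[1] * f)
        ramp = np.exp(-2j * np.pi * (fy[:, None] * sy + fy[None, :] * sx))
        data.append(ifft2c(k * ramp))
    return ImageSeries(data=np.stack(data), pixel_spacing=(dx, dx),
                       frame_times=np.arange(frames, dtype=float),
                       provenance="reference")


class TestExtractHarmonicPhase:
    def test_static_series_gives_identical_phase_maps(self):
        series = synthetic_tagged_series(frames=3)
        ps = extract_harmonic_phase(series, tag_axis=1, d_tag=D_TAG)
        assert np.allclose(ps.phase[0], ps.phase[1], atol=1e-6)
        assert np.allclose(ps.phase[0], ps.phase[2], atol=1e-6)

    def test_quarter_period_translation_shifts_phase_by_half_pi(self):
        # moving the object by +d/4 along the tag axis lowers the harmonic
        # phase at a fixed location by pi/2 (shift theorem)
        series = synthetic_tagged_series(frames=2, shift_mm=(0.0, D_TAG / 4))
        ps = extract_harmonic_phase(series, tag_axis=1, d_tag=D_TAG)
        n = ps.phase.shape[1] // 2
        c = ps.phase.shape[2] // 2
        sl = (slice(n - 8, n + 8), slice(c - 8, c + 8))
        dphi = np.angle(np.exp(1j * (ps.phase[1][sl] - ps.phase[0][sl])))
        assert np.abs(np.median(dphi) + np.pi / 2) < 0.01

    def test_untagged_image_raises(self):
        series = synthetic_tagged_series(frames=1)
        series.data = np.abs(series.data) * 0 + 1.0  # flat image, no harmonic
        with pytest.raises(ValueError, match="noise floor"):
            extract_harmonic_phase(series, tag_axis=1, d_tag=D_TAG)

    def test_harmonic_frequency_recorded(self):
        series = synthetic_tagged_series(frames=1)
        ps = extract_harmonic_phase(series, tag_axis=1, d_tag=D_TAG)
        assert ps.harmonic_freq == pytest.approx(1.0 / D_TAG)


class TestHarpTrack:
    def _phase_pair(self, frames=3, shift_mm=(0.0, 0.0)):
        sx = synthetic_tagged_series(frames=frames, shift_mm=shift_mm)
        # the orthogonal-tag series is built by transposing, which swaps the
        # displacement components, so generate it with them pre-swapped
        sy = synthetic_tagged_series(frames=frames,
                                     shift_mm=(shift_mm[1], shift_mm[0]))
        sy.data = np.transpose(sy.data, (0, 2, 1))  # tags along y
        px = extract_harmonic_phase(sx, tag_axis=1, d_tag=D_TAG)
        py = extract_harmonic_phase(sy, tag_axis=0, d_tag=D_TAG)
        return px, py

    def test_static_series_zero_displacement(self):
        px, py = self._phase_pair()
        pts = circle_contour(25.0, 32)
        traj = harp_track(pts, px, py, d_tag=D_TAG)
        disp = np.linalg.norm(traj.positions[-1] - traj.positions[0], axis=1)
        assert disp.max() < 1e-3

    def test_rigid_translation_recovered(self):
        shift = (1.0, -0.5)  # mm per frame
        px, py = self._phase_pair(frames=2, shift_mm=shift)
        pts = circle_contour(25.0, 32)
        traj = harp_track(pts, px, py, d_tag=D_TAG)
        disp = traj.positions[1] - traj.positions[0]
        err = np.linalg.norm(disp - np.array(shift), axis=1)
        assert np.median(err) < 0.05

    def test_phantom_end_systole_matches_analytic_deformation(
            self, desk_phantom, desk_snapshot_series):
        cfg, _, motion = desk_phantom
        ref_x, ref_y = desk_snapshot_series
        px = extract_harmonic_phase(ref_x, 1, D_TAG)
        py = extract_harmonic_phase(ref_y, 0, D_TAG)
        contour = circle_contour((cfg.ri0 + cfg.ro0) / 2, 48)
        traj = harp_track(contour, px, py, d_tag=D_TAG,
                          frame_times=ref_x.frame_times)
        f_es = int(np.argmin(np.abs(ref_x.frame_times - motion.t_es)))
        truth = deform_point(motion, contour, ref_x.frame_times[f_es])
        err = np.linalg.norm(traj.positions[f_es] - truth, axis=1)
        assert np.median(err) < 0.2

    def test_same_axis_series_rejected(self):
        sx = synthetic_tagged_series(frames=2)
        px = extract_harmonic_phase(sx, tag_axis=1, d_tag=D_TAG)
        with pytest.raises(ValueError):
            harp_track(circle_contour(25.0, 32), px, px, d_tag=D_TAG)


class TestMidwallGcs:
    def _identity_traj(self, n_pts=32, frames=4):
        pts = circle_contour(25.0, n_pts)
        pos = np.repeat(pts[None], frames, axis=0)
        return MaterialTrajectory(positions=pos,
                                  converged=np.ones((frames, n_pts), bool),
                                  frame_times=np.arange(frames, dtype=float))

    def test_identity_gives_zero_curve(self):
        curve = midwall_gcs(self._identity_traj())
        assert np.allclose(curve.gcs, 0.0, atol=1e-12)

    def test_pure_rotation_gives_zero(self):
        pts = circle_contour(25.0, 32)
        c, s = np.cos(0.4), np.sin(0.4)
        rot = pts @ np.array([[c, s], [-s, c]])
        pos = np.stack([pts, rot])
        traj = MaterialTrajectory(positions=pos,
                                  converged=np.ones((2, 32), bool),
                                  frame_times=np.array([0.0, 1.0]))
        assert abs(midwall_gcs(traj).gcs[1]) < 1e-3

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            midwall_gcs(self._identity_traj(n_pts=12))

    def test_summary_mean_of_slice_peaks(self):
        from rttag.strain import StrainCurve
        curves = [StrainCurve(gcs=np.array([0.0, peak]),
                              frame_times=np.array([0.0, 1.0]), slice_id=sid)
                  for peak, sid in [(-0.15, "b"), (-0.18, "m"), (-0.21, "a")]]
        summary = summarize_gcs(curves)
        assert summary.global_gcs == pytest.approx(-0.18)
        assert summary.n_slices == 3
        single = summarize_gcs(curves[:1])
        assert single.global_gcs == pytest.approx(-0.15)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_gcs([])


class TestRigidMotionInvariance:
    def test_gcs_unchanged_under_series_translation(self, desk_phantom,
                                                    desk_snapshot_series):
        cfg, _, _ = desk_phantom
        ref_x, ref_y = desk_snapshot_series
        contour = circle_contour((cfg.ri0 + cfg.ro0) / 2, 48)
        base, _ = measure_gcs(ref_x, ref_y, contour, D_TAG)

        def shifted(series, dy, dx):
            n = series.data.shape[-1]
            f = np.fft.fftshift(np.fft.fftfreq(n, d=2.0))
            ramp = np.exp(-2j * np.pi * (f[:, None] * dy + f[None, :] * dx))
            data = ifft2c(fft2c(series.data) * ramp)
            return ImageSeries(data=data, pixel_spacing=series.pixel_spacing,
                               frame_times=series.frame_times,
                               provenance=series.provenance,
                               pe_axis=series.pe_axis, fov=series.fov)

        moved, _ = measure_gcs(shifted(ref_x, 3.0, -2.0),
                               shifted(ref_y, 3.0, -2.0),
                               contour + np.array([3.0, -2.0]), D_TAG)
        n = min(len(base.gcs), len(moved.gcs))
        assert np.nanmax(np.abs(base.gcs[:n] - moved.gcs[:n])) < 1e-3


class TestPipelineRecovery:
    def _run(self, d_tag, noise=0.0, seed=0, n=DESK_N, window=700.0,
             coils=8, cs_iters=40, px=2.0):
        cfg = PhantomConfig(matrix=n, pixel_spacing=px)
        tissue, motion = build_phantom(cfg)
        maps = make_coil_sensitivities(n, coils) if coils > 1 else None
        prot_x = SequenceProtocol(matrix=n, fov=n * px, tag_axis="col",
                                  window_ms=window, d_tag=d_tag)
        prot_y = SequenceProtocol(matrix=n, fov=n * px, tag_axis="row",
                                  window_ms=window, d_tag=d_tag)
        frames = timing_summary(prot_x).frames_per_window
        rng = np.random.default_rng(seed)
        plan_x = make_sampling_plan(n, 2, 6, frames, seed=int(rng.integers(2**31)))
        plan_y = make_sampling_plan(n, 2, 6, frames, seed=int(rng.integers(2**31)))
        ks_x = acquire_series(tissue, motion, prot_x, plan_x, noise_sd=noise,
                              rng=np.random.default_rng(seed + 1), coil_maps=maps)
        ks_y = acquire_series(tissue, motion, prot_y, plan_y, noise_sd=noise,
                              rng=np.random.default_rng(seed + 2), coil_maps=maps)
        sx = zero_pad_enhance(cs_recon(ks_x, plan_x, iterations=cs_iters), n)
        sy = zero_pad_enhance(cs_recon(ks_y, plan_y, iterations=cs_iters), n)
        contour = circle_contour((cfg.ri0 + cfg.ro0) / 2, 48)
        curve, _ = measure_gcs(sx, sy, contour, d_tag)
        return abs(float(np.nanmin(curve.gcs)) - cfg.gcs_peak)

    @pytest.mark.parametrize("d_tag", [8.0, 10.0])
    def test_recovery_independent_of_tag_spacing(self, d_tag):
        # 1.5 mm pixels so every spacing keeps its carrier clear of Nyquist
        assert self._run(d_tag, seed=11, n=128, px=1.5) <= 0.02

    def test_recovery_at_minimum_tag_spacing(self):
        # 6 mm tags sit at the resolution-limited minimum spacing of the
        # technique; recovery is noisier there, so assert the median over
        # three mask realizations at a wider bound
        errs = [self._run(6.0, seed=s, n=128, px=1.5) for s in (11, 12, 13)]
        assert np.median(errs) <= 0.035

    def test_recovery_degrades_monotonically_with_noise(self):
        # medians over 10 seeds per noise level, 4-point ladder
        ladder = [0.0, 0.003, 0.006, 0.012]
        medians = []
        for noise in ladder:
            errs = [self._run(8.0, noise=noise, seed=100 + s, n=64,
                              window=500.0, coils=1, cs_iters=30)
                    for s in range(10)]
            medians.append(np.median(errs))
        assert all(b >= a - 2e-4 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]
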