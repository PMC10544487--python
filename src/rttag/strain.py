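"""Harmonic-phase (HARP) strain analysis of tagged image series.

The first spectral harmonic of the tag pattern is isolated with a
raised-cosine bandpass; its phase is a material coordinate that moves with
the tissue.  Tracking a point means finding, frame by frame, the location
whose pair of harmonic phases (one per tag-encoding axis, from two
orthogonal line-tag acquisitions) matches the point's reference pair.
Mid-wall global circumferential strain (GCS) is then the relative change of
the closed-polygon perimeter through the tracked mid-wall points; per-slice
curves are averaged into a global value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .fourier import fft2c, ifft2c
from .recon import ImageSeries


@dataclass
class PhaseSeries:
    """Wrapped harmonic phase maps for one tag-encoding axis."""

    phase: np.ndarray  # (frames, ny, nx), values in (-pi, pi]
    tag_axis: int  # image axis along which the tag pattern varies
    harmonic_freq: float  # 1/mm
    band_halfwidth: float  # 1/mm
    pixel_spacing: tuple[float, float]

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]


@dataclass
class MaterialTrajectory:
    """Tracked material points: (frames, n_points, 2) positions in mm (y, x)."""

    positions: np.ndarray
    converged: np.ndarray  # (frames, n_points) bool
    frame_times: np.ndarray

    @property
    def reference(self) -> np.ndarray:
        return self.positions[0]


@dataclass
class StrainCurve:
    gcs: np.ndarray  # per-frame mid-wall GCS; NaN where undefined
    frame_times: np.ndarray
    slice_id: str = "slice0"
    converged_fraction: np.ndarray | None = None


@dataclass
class StrainSummary:
    peaks: list[float]  # per-slice peak (most negative) GCS
    global_gcs: float
    n_slices: int


def _raised_cosine_window(n: int, dx: float, k0: float, bw: float) -> np.ndarray:
    # clip the passband to the sampled bandwidth so a harmonic close to
    # Nyquist does not wrap into the negative-frequency half
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    bw = min(bw, freqs.max() - k0, k0)
    w = 0.5 * (1 + np.cos(np.pi * (freqs - k0) / bw))
    w[np.abs(freqs - k0) >= bw] = 0.0
    return w


def tag_minima_spacing(profile: np.ndarray, dx: float,
                       prominence: float = 0.2) -> float:
    """Median distance between adjacent deep minima of an Mz tag profile.

    ``prominence`` (relative to the profile range) rejects the shallow
    plateau ripple of binomial tag patterns.
    """
    rng = profile.max() - profile.min()
    idx, _ = find_peaks(-profile, prominence=prominence * rng)
    if len(idx) < 2:
        raise ValueError("fewer than two tag minima found")
    return float(np.median(np.diff(idx)) * dx)


def extract_harmonic_phase(series: ImageSeries, tag_axis: int, d_tag: float,
                           band_halfwidth: float | None = None,
                           min_harmonic_ratio: float = 0.05,
                           oversample: int = 2) -> PhaseSeries:
    """Isolate the first tag harmonic and return its wrapped phase per frame.

    A raised-cosine window of half-width ``band_halfwidth`` (default
    0.6 / d_tag, in 1/mm — wide enough to keep the motion-induced sidebands
    that carry large systolic displacements, while still excluding DC and
    the -1 harmonic) is centered on the +1 harmonic along the tag axis.  Frames whose harmonic amplitude falls below
    ``min_harmonic_ratio`` of the DC amplitude raise an error.

    ``oversample`` zero-pads the bandpassed spectrum along the tag axis
    before the inverse transform: the returned phase maps are sampled on an
    ``oversample``-times finer grid (exact sinc interpolation), which keeps
    the phase carrier well resolved even for tag spacings near Nyquist.
    """
    if d_tag <= 0:
        raise ValueError("tag spacing must be positive")
    bw = band_halfwidth if band_halfwidth is not None else 0.7 / d_tag
    axis = 1 + tag_axis
    n = series.data.shape[axis]
    dx = series.pixel_spacing[tag_axis]
    k0 = 1.0 / d_tag
    if k0 >= np.fft.fftshift(np.fft.fftfreq(n, d=dx)).max():
        raise ValueError("tag harmonic outside the sampled bandwidth")
    w = _raised_cosine_window(n, dx, k0, bw)
    shape = [1, 1, 1]
    shape[axis] = n
    w = w.reshape(shape)

    k = fft2c(series.data)
    other = 1 + (1 - tag_axis)
    dc_amp = np.abs(k).max(axis=(1, 2))
    harm = k * w
    harm_amp = np.abs(harm).max(axis=(1, 2))
    low = harm_amp < min_harmonic_ratio * dc_amp
    if low.any():
        bad = int(np.flatnonzero(low)[0])
        raise ValueError(f"tag harmonic below the noise floor in frame {bad}")
    spacing = list(series.pixel_spacing)
    if oversample > 1:
        pad = (oversample - 1) * n
        widths = [(0, 0), (0, 0), (0, 0)]
        widths[axis] = (pad - pad // 2, pad // 2)
        harm = np.pad(harm, widths)
        spacing[tag_axis] /= oversample
    comp = ifft2c(harm)
    return PhaseSeries(phase=np.angle(comp), tag_axis=tag_axis,
                       harmonic_freq=k0, band_halfwidth=bw,
                       pixel_spacing=tuple(spacing))


class _PhaseField:
    """Sub-pixel evaluation of a wrapped phase map and its gradient."""

    def __init__(self, phase: np.ndarray, spacing: tuple[float, float]):
        self.spacing = spacing
        self.cos = np.cos(phase)
        self.sin = np.sin(phase)
        # wrapped one-pixel differences, averaged; a two-pixel central
        # difference would hit the pi ambiguity on the tag carrier
        def _wdiff(ax):
            fwd = np.angle(np.exp(1j * (np.roll(phase, -1, ax) - phase)))
            bwd = np.angle(np.exp(1j * (phase - np.roll(phase, 1, ax))))
            return (fwd + bwd) / (2 * spacing[ax])

        gy = _wdiff(0)
        gx = _wdiff(1)
        self.gy, self.gx = gy, gx
        self.ny, self.nx = phase.shape

    def _bilinear(self, arr, iy, ix):
        iy = np.clip(iy, 0, self.ny - 1.001)
        ix = np.clip(ix, 0, self.nx - 1.001)
        y0 = np.floor(iy).astype(int)
        x0 = np.floor(ix).astype(int)
        fy, fx = iy - y0, ix - x0
        return ((1 - fy) * (1 - fx) * arr[y0, x0] + (1 - fy) * fx * arr[y0, x0 + 1]
                + fy * (1 - fx) * arr[y0 + 1, x0] + fy * fx * arr[y0 + 1, x0 + 1])

    def phase_at(self, pts_mm: np.ndarray) -> np.ndarray:
        iy = pts_mm[:, 0] / self.spacing[0] + self.ny / 2
        ix = pts_mm[:, 1] / self.spacing[1] + self.nx / 2
        c = self._bilinear(self.cos, iy, ix)
        s = self._bilinear(self.sin, iy, ix)
        return np.arctan2(s, c)

    def grad_at(self, pts_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        iy = pts_mm[:, 0] / self.spacing[0] + self.ny / 2
        ix = pts_mm[:, 1] / self.spacing[1] + self.nx / 2
        return self._bilinear(self.gy, iy, ix), self._bilinear(self.gx, iy, ix)


def harp_track(points0: np.ndarray, phase_x: PhaseSeries, phase_y: PhaseSeries,
               d_tag: float | None = None, max_iter: int = 20,
               tol: float = 1e-3, frame_times: np.ndarray | None = None) -> MaterialTrajectory:
    """Track material points by harmonic-phase constancy.

    ``phase_x`` encodes displacement along image axis 1 (its tags vary along
    x); ``phase_y`` along axis 0.  For each point and successive frame a
    Newton iteration, seeded from the previous frame, finds the location
    whose wrapped phase pair equals the reference pair; steps are clamped to
    half a tag spacing to avoid jumping to a neighbouring tag.
    """
    ext_x = tuple(s * d for s, d in zip(phase_x.phase.shape[1:], phase_x.pixel_spacing))
    ext_y = tuple(s * d for s, d in zip(phase_y.phase.shape[1:], phase_y.pixel_spacing))
    if not np.allclose(ext_x, ext_y):
        raise ValueError("phase series cover different physical extents")
    if phase_x.tag_axis == phase_y.tag_axis:
        raise ValueError("need two orthogonal tag-encoding axes")
    pts0 = np.asarray(points0, dtype=float)
    n_frames = phase_x.n_frames
    n_pts = len(pts0)
    d_tag = d_tag if d_tag is not None else 1.0 / phase_x.harmonic_freq
    max_step = d_tag / 2.0

    fields_x = [_PhaseField(phase_x.phase[f], phase_x.pixel_spacing) for f in range(n_frames)]
    fields_y = [_PhaseField(phase_y.phase[f], phase_y.pixel_spacing) for f in range(n_frames)]

    ref_px = fields_x[0].phase_at(pts0)
    ref_py = fields_y[0].phase_at(pts0)

    positions = np.zeros((n_frames, n_pts, 2))
    converged = np.zeros((n_frames, n_pts), dtype=bool)
    positions[0] = pts0
    converged[0] = True

    cur = pts0.copy()
    for f in range(1, n_frames):
        fx, fy = fields_x[f], fields_y[f]
        p = cur.copy()
        active = np.ones(n_pts, dtype=bool)
        for it in range(max_iter):
            # damp late iterations: the interpolated Jacobian is only
            # piecewise continuous, and undamped Newton can limit-cycle
            # across cell boundaries
            damp = 1.0 if it < max_iter // 2 else 0.5
            rx = np.angle(np.exp(1j * (fx.phase_at(p) - ref_px)))
            ry = np.angle(np.exp(1j * (fy.phase_at(p) - ref_py)))
            res = np.hypot(rx, ry)
            done = res < tol
            active = active & ~done
            if not active.any():
                break
            gyx, gxx = fx.grad_at(p)  # d(phase_x)/dy, d(phase_x)/dx
            gyy, gxy = fy.grad_at(p)
            det = gxx * gyy - gyx * gxy
            det = np.where(np.abs(det) < 1e-12, np.inf, det)
            dy = (-gxx * ry + gxy * rx) / det
            dx = (-gyy * rx + gyx * ry) / det
            step = np.hypot(dy, dx)
            scale = damp * np.where(step > max_step, max_step / np.maximum(step, 1e-30), 1.0)
            p[active, 0] += (dy * scale)[active]
            p[active, 1] += (dx * scale)[active]
        rx = np.angle(np.exp(1j * (fx.phase_at(p) - ref_px)))
        ry = np.angle(np.exp(1j * (fy.phase_at(p) - ref_py)))
        ok = np.hypot(rx, ry) < tol
        positions[f] = p
        converged[f] = ok
        if ok.mean() < 0.5:
            raise ValueError(f"more than half the points failed to converge in frame {f}")
        cur = p
    times = frame_times if frame_times is not None else np.arange(n_frames, dtype=float)
    return MaterialTrajectory(positions=positions, converged=converged,
                              frame_times=np.asarray(times, dtype=float))


def _perimeter(pts: np.ndarray) -> float:
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def midwall_gcs(trajectory: MaterialTrajectory, slice_id: str = "slice0",
                min_converged: float = 0.75) -> StrainCurve:
    """GCS(t) = P(t)/P(0) - 1 from the closed-polygon perimeter through the
    converged tracked points (the same subset is used at t and 0, so partial
    convergence does not bias the ratio)."""
    n_frames, n_pts, _ = trajectory.positions.shape
    if n_pts < 24:
        raise ValueError("need at least 24 contour points")
    gcs = np.full(n_frames, np.nan)
    frac = trajectory.converged.mean(axis=1)
    for f in range(n_frames):
        ok = trajectory.converged[f]
        if ok.mean() < min_converged or ok.sum() < 24:
            continue
        p0 = _perimeter(trajectory.positions[0][ok])
        pt = _perimeter(trajectory.positions[f][ok])
        gcs[f] = pt / p0 - 1.0
    gcs[0] = 0.0
    return StrainCurve(gcs=gcs, frame_times=trajectory.frame_times,
                       slice_id=slice_id, converged_fraction=frac)


def summarize_gcs(curves: list[StrainCurve]) -> StrainSummary:
    """Per-slice peak (most negative) GCS and their unweighted mean."""
    if not curves:
        raise ValueError("no strain curves supplied")
    peaks = [float(np.nanmin(c.gcs)) for c in curves]
    return StrainSummary(peaks=peaks, global_gcs=float(np.mean(peaks)),
                         n_slices=len(curves))


def circle_contour(radius: float, n_points: int = 96,
                   center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Ordered (y, x) mm points on a circle — the simulated mid-wall contour."""
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return np.stack([center[0] + radius * np.sin(th),
                     center[1] + radius * np.cos(th)], axis=1)


def harmonic_fade_frame(series: ImageSeries, tag_axis: int, d_tag: float,
                        band_halfwidth: float | None = None,
                        min_harmonic_ratio: float = 0.05) -> int:
    """First frame whose tag harmonic drops below the usable threshold
    (series length if none does).  Tag fading limits the analyzable window."""
    bw = band_halfwidth if band_halfwidth is not None else 0.7 / d_tag
    axis = 1 + tag_axis
    n = series.data.shape[axis]
    dx = series.pixel_spacing[tag_axis]
    w = _raised_cosine_window(n, dx, 1.0 / d_tag, bw)
    shape = [1, 1, 1]
    shape[axis] = n
    k = fft2c(series.data)
    harm = np.abs(k * w.reshape(shape)).max(axis=(1, 2))
    dc = np.abs(k).max(axis=(1, 2))
    bad = np.flatnonzero(harm < min_harmonic_ratio * dc)
    return int(bad[0]) if len(bad) else series.n_frames


def measure_gcs(series_x: ImageSeries, series_y: ImageSeries,
                contour: np.ndarray, d_tag: float,
                slice_id: str = "slice0") -> tuple[StrainCurve, MaterialTrajectory]:
    """Convenience pipeline: two orthogonal-tag series -> strain curve.

    Frames past the point where either series' tag harmonic has faded below
    the noise floor are excluded from the analysis.
    """
    nx = harmonic_fade_frame(series_x, 1, d_tag)
    ny = harmonic_fade_frame(series_y, 0, d_tag)
    n_ok = min(nx, ny)
    if n_ok < 2:
        raise ValueError("tag harmonic unusable from the first frames on")
    sx = ImageSeries(data=series_x.data[:n_ok], pixel_spacing=series_x.pixel_spacing,
                     frame_times=series_x.frame_times[:n_ok],
                     provenance=series_x.provenance, pe_axis=series_x.pe_axis,
                     fov=series_x.fov)
    sy = ImageSeries(data=series_y.data[:n_ok], pixel_spacing=series_y.pixel_spacing,
                     frame_times=series_y.frame_times[:n_ok],
                     provenance=series_y.provenance, pe_axis=series_y.pe_axis,
                     fov=series_y.fov)
    px = extract_harmonic_phase(sx, tag_axis=1, d_tag=d_tag)
    py = extract_harmonic_phase(sy, tag_axis=0, d_tag=d_tag)
    n = min(px.n_frames, py.n_frames)
    px.phase = px.phase[:n]
    py.phase = py.phase[:n]
    traj = harp_track(contour, px, py, d_tag=d_tag,
                      frame_times=series_x.frame_times[:n])
    return midwall_gcs(traj, slice_id=slice_id), traj
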