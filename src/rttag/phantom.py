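"""Parametric short-axis left-ventricle phantom with analytic contraction.

The phantom is a myocardial annulus (inner radius ``ri0``, outer radius
``ro0``) embedded in a square grid, with a blood pool inside and optional
epicardial fat ring.  Contraction is an incompressible radial mapping: the
inner radius follows a smooth activation waveform ``g(t)`` and the outer
radius is set by wall-area preservation, so mid-wall circumferential strain
is known in closed form at every time point.  This exact ground truth is what
the tracking pipeline is validated against.

Coordinate convention: physical coordinates in mm, origin at the grid
centre; pixel index ``i`` maps to coordinate ``(i - N/2) * pixel_spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

LABELS = {"background": 0, "myocardium": 1, "blood": 2, "fat": 3}

# Literature-typical 3 T relaxation times (ms); see docs/methods.md.
TISSUE_PROPERTIES = {
    "myocardium": dict(pd=0.8, t1=1400.0, t2=45.0, df=0.0),
    "blood": dict(pd=0.9, t1=1900.0, t2=250.0, df=0.0),
    "fat": dict(pd=1.0, t1=380.0, t2=100.0, df=-440.0),
    "background": dict(pd=0.0, t1=1.0, t2=1.0, df=0.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue configuration of the digital phantom."""

    matrix: int = 176
    pixel_spacing: float = 2.0  # mm
    ri0: float = 20.0  # end-diastolic endocardial radius, mm
    ro0: float = 35.0  # end-diastolic epicardial radius, mm
    gcs_peak: float = -0.18  # peak mid-wall circumferential strain
    period_ms: float = 1000.0  # cardiac period (60 bpm)
    systolic_fraction: float = 0.35
    onset_delay_ms: float = 50.0  # electromechanical delay after trigger
    waveform: str = "raised_cosine"
    drift_amp_mm: float = 0.0  # rigid respiratory drift amplitude
    drift_period_ms: float = 4000.0
    torsion_deg: float = 0.0
    fat_ring: bool = False
    fat_thickness_mm: float = 6.0
    blood_suppression: float = 1.0  # multiplies blood proton density

    @property
    def fov(self) -> float:
        return self.matrix * self.pixel_spacing


@dataclass
class TissueMap:
    """Per-pixel tissue property maps on the phantom grid."""

    pd: np.ndarray  # proton density (a.u.)
    t1: np.ndarray  # ms
    t2: np.ndarray  # ms
    df: np.ndarray  # off-resonance, Hz
    labels: np.ndarray  # int codes per LABELS
    pixel_spacing: float  # mm, isotropic

    @property
    def matrix(self) -> int:
        return self.pd.shape[0]

    @property
    def fov(self) -> float:
        return self.matrix * self.pixel_spacing

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinate grids in mm, origin at centre."""
        n = self.matrix
        ax = (np.arange(n) - n / 2) * self.pixel_spacing
        return np.meshgrid(ax, ax, indexing="ij")


@dataclass(frozen=True)
class MotionModel:
    """Analytic incompressible contraction of the annulus.

    ``ri(t) = ri0 * (1 + g(t) * kappa)`` with activation ``g`` rising
    from 0 to 1 over the systolic interval; ``ro`` follows from wall-area
    preservation; ``kappa`` is solved so that the mid-wall radius ratio at
    end-systole equals ``1 + gcs_peak``.
    """

    ri0: float
    ro0: float
    gcs_peak: float
    period_ms: float
    systolic_fraction: float
    onset_delay_ms: float = 0.0
    waveform: str = "raised_cosine"
    drift_amp_mm: float = 0.0
    drift_period_ms: float = 4000.0
    torsion_deg: float = 0.0
    kappa: float = field(init=False, default=0.0)

    def __post_init__(self):
        if not 0 < self.ri0 < self.ro0:
            raise ValueError("need 0 < ri0 < ro0")
        if not -1.0 < self.gcs_peak <= 0.0:
            raise ValueError("gcs_peak must lie in (-1, 0]")
        if self.period_ms <= 0:
            raise ValueError("period must be positive")
        object.__setattr__(self, "kappa", self._solve_kappa())

    def _solve_kappa(self) -> float:
        # kappa scales the end-systolic inner radius so that the *material*
        # mid-wall circle (reference radius rm0 = (ri0+ro0)/2) contracts by
        # exactly gcs_peak: sqrt(rm0^2 - ri0^2 + ri_es^2) = (1+gcs_peak)*rm0.
        # The material definition is what a tag-tracking method measures; the
        # instantaneous geometric mid-radius (ri+ro)/2 is not materially
        # conserved under the incompressible map.
        if self.gcs_peak == 0.0:
            return 0.0
        rm0 = (self.ri0 + self.ro0) / 2.0
        ri_es_sq = self.ri0**2 - rm0**2 * (1.0 - (1.0 + self.gcs_peak) ** 2)
        if ri_es_sq <= 0:
            raise ValueError("gcs_peak too strong: inner radius would vanish")
        return float(np.sqrt(ri_es_sq) / self.ri0 - 1.0)

    @property
    def t_es(self) -> float:
        """Time of end-systole (peak contraction), ms."""
        return self.onset_delay_ms + self.systolic_fraction * self.period_ms

    def activation(self, t) -> np.ndarray:
        """Contraction waveform g(t) in [0, 1]; g(0)=0, g(t_es)=1."""
        t = np.asarray(t, dtype=float)
        tc = np.mod(t, self.period_ms)
        tc = tc - self.onset_delay_ms
        ts = self.systolic_fraction * self.period_ms
        td = self.period_ms - self.onset_delay_ms - ts  # diastolic return
        g = np.zeros_like(tc)
        rise = (tc >= 0) & (tc < ts)
        g = np.where(rise, 0.5 * (1 - np.cos(np.pi * tc / ts)), g)
        fall = tc >= ts
        g = np.where(fall, 0.5 * (1 + np.cos(np.pi * (tc - ts) / td)), g)
        return g

    def radii(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Inner and outer wall radius (mm) at time t."""
        g = self.activation(t)
        ri = self.ri0 * (1.0 + g * self.kappa)
        ro = np.sqrt(ri * ri + self.ro0**2 - self.ri0**2)
        return ri, ro

    def drift(self, t) -> tuple[float, float]:
        """Rigid translation (dy, dx) in mm at time t."""
        if self.drift_amp_mm == 0.0:
            return 0.0, 0.0
        d = self.drift_amp_mm * np.sin(2 * np.pi * np.asarray(t) / self.drift_period_ms)
        return float(d), 0.0

    def true_gcs(self, t) -> np.ndarray:
        """Ground-truth mid-wall circumferential strain at time t: relative
        radius change of the material circle that starts at (ri0+ro0)/2."""
        ri, _ = self.radii(t)
        rm0 = (self.ri0 + self.ro0) / 2.0
        rm = np.sqrt(rm0**2 - self.ri0**2 + ri * ri)
        return rm / rm0 - 1.0


def build_phantom(config: PhantomConfig) -> tuple[TissueMap, MotionModel]:
    """Construct the tissue maps and motion model for a configuration."""
    n = config.matrix
    half_fov = config.fov / 2.0
    ro_out = config.ro0 + (config.fat_thickness_mm if config.fat_ring else 0.0)
    if ro_out >= half_fov:
        raise ValueError("outer radius does not fit inside the field of view")
    if config.ri0 >= config.ro0:
        raise ValueError("need ri0 < ro0")
    for name in ("myocardium", "blood", "fat"):
        p = TISSUE_PROPERTIES[name]
        if p["t1"] <= 0 or p["t2"] <= 0 or p["t1"] <= p["t2"]:
            raise ValueError(f"invalid relaxation times for {name}")

    ax = (np.arange(n) - n / 2) * config.pixel_spacing
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(yy, xx)

    labels = np.zeros((n, n), dtype=np.int8)
    labels[r < config.ri0] = LABELS["blood"]
    labels[(r >= config.ri0) & (r < config.ro0)] = LABELS["myocardium"]
    if config.fat_ring:
        labels[(r >= config.ro0) & (r < ro_out)] = LABELS["fat"]

    t1 = np.full((n, n), 1.0)
    t2 = np.full((n, n), 1.0)
    df = np.zeros((n, n))
    # relaxation/off-resonance maps extend through the partial-volume rims
    # so every pixel with nonzero proton density relaxes like its tissue
    rim = 1.5 * config.pixel_spacing + config.pixel_spacing / 2
    regions = [("blood", r < config.ri0),
               ("myocardium", (r >= config.ri0) & (r < config.ro0 + rim))]
    if config.fat_ring:
        regions.append(("fat", (r >= config.ro0 + rim) & (r < ro_out + rim)))
    for name, sel in regions:
        p = TISSUE_PROPERTIES[name]
        t1[sel] = p["t1"]
        t2[sel] = p["t2"]
        df[sel] = p["df"]

    # proton density with anti-aliased (partial-volume) edges: a 1.5-pixel
    # linear ramp at each tissue boundary keeps pull-back interpolation
    # accurate where the hard label map would ring
    w = 1.5 * config.pixel_spacing

    def ramp(x):
        return np.clip(x / w + 0.5, 0.0, 1.0)

    blood_frac = ramp(config.ri0 - r)
    myo_frac = ramp(r - config.ri0) * ramp(config.ro0 - r)
    pd = (TISSUE_PROPERTIES["myocardium"]["pd"] * myo_frac
          + TISSUE_PROPERTIES["blood"]["pd"] * config.blood_suppression * blood_frac)
    if config.fat_ring:
        fat_frac = ramp(r - config.ro0) * ramp(ro_out - r)
        pd = pd + TISSUE_PROPERTIES["fat"]["pd"] * fat_frac

    tissue = TissueMap(pd=pd, t1=t1, t2=t2, df=df, labels=labels,
                       pixel_spacing=config.pixel_spacing)
    motion = MotionModel(
        ri0=config.ri0, ro0=config.ro0, gcs_peak=config.gcs_peak,
        period_ms=config.period_ms, systolic_fraction=config.systolic_fraction,
        onset_delay_ms=config.onset_delay_ms, waveform=config.waveform,
        drift_amp_mm=config.drift_amp_mm, drift_period_ms=config.drift_period_ms,
        torsion_deg=config.torsion_deg,
    )
    return tissue, motion


def deform_point(motion: MotionModel, points, t: float) -> np.ndarray:
    """Map reference material points (mm, shape (..., 2) as (y, x)) to their
    position at time t under the incompressible contraction."""
    if t < 0:
        raise ValueError("t must be non-negative")
    pts = np.asarray(points, dtype=float)
    y0, x0 = pts[..., 0], pts[..., 1]
    r0 = np.hypot(y0, x0)
    theta0 = np.arctan2(y0, x0)
    ri, ro = motion.radii(t)
    g = motion.activation(t)
    inside = r0 < motion.ri0
    with np.errstate(invalid="ignore"):
        r_wall = np.sqrt(np.maximum(r0 * r0 - motion.ri0**2 + ri * ri, 0.0))
    r_new = np.where(inside, r0 * ri / motion.ri0, r_wall)
    theta = theta0 + np.deg2rad(motion.torsion_deg) * g
    dy, dx = motion.drift(t)
    out = np.empty_like(pts)
    out[..., 0] = r_new * np.sin(theta) + dy
    out[..., 1] = r_new * np.cos(theta) + dx
    return out


def inverse_map_indices(motion: MotionModel, tissue: TissueMap, t: float) -> np.ndarray:
    """Reference-grid index coordinates of each spatial pixel at time t.

    Returns an array of shape (2, N, N) suitable for
    ``scipy.ndimage.map_coordinates`` (pull-back sampling).
    """
    n = tissue.matrix
    yy, xx = tissue.coords()
    dy, dx = motion.drift(t)
    y = yy - dy
    x = xx - dx
    g = motion.activation(t)
    tors = np.deg2rad(motion.torsion_deg) * g
    if tors != 0.0:
        c, s = np.cos(-tors), np.sin(-tors)
        y, x = c * y + s * x, -s * y + c * x  # undo rotation about centre
    r = np.hypot(y, x)
    ri, ro = motion.radii(t)
    inside = r < ri
    with np.errstate(invalid="ignore"):
        r0_wall = np.sqrt(np.maximum(r * r - ri * ri + motion.ri0**2, 0.0))
    r0 = np.where(inside, r * motion.ri0 / max(ri, 1e-9), r0_wall)
    scale = np.where(r > 1e-12, r0 / np.maximum(r, 1e-12), 0.0)
    y0 = y * scale
    x0 = x * scale
    iy = y0 / tissue.pixel_spacing + n / 2
    ix = x0 / tissue.pixel_spacing + n / 2
    return np.stack([iy, ix])


def warp_image(image: np.ndarray, indices: np.ndarray, order: int = 3) -> np.ndarray:
    """Pull-back resample an image (real or complex) at the given reference
    index coordinates; points outside the grid map to exactly zero."""
    if np.iscomplexobj(image):
        re = ndimage.map_coordinates(image.real, indices, order=order, cval=0.0)
        im = ndimage.map_coordinates(image.imag, indices, order=order, cval=0.0)
        return re + 1j * im
    return ndimage.map_coordinates(image, indices, order=order, cval=0.0)


@dataclass
class ObjectFrame:
    """Complex-valued object (magnetization-weighted image) at one instant."""

    data: np.ndarray
    time_ms: float
    pixel_spacing: float


def render_object(tissue: TissueMap, motion: MotionModel, t: float,
                  image: np.ndarray | None = None) -> ObjectFrame:
    """Render the deformed object at time t by pull-back sampling.

    By default the proton-density map is warped; pass ``image`` to warp an
    arbitrary reference-frame map (e.g. tagged magnetization).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    src = tissue.pd if image is None else image
    idx = inverse_map_indices(motion, tissue, t)
    data = warp_image(src, idx)
    return ObjectFrame(data=data, time_ms=float(t), pixel_spacing=tissue.pixel_spacing)


def true_gcs(motion: MotionModel, t) -> np.ndarray:
    """Ground-truth mid-wall global circumferential strain at time t."""
    return motion.true_gcs(t)
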