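"""Cartesian phase-encode sampling plans: outer k-space truncation combined
with incoherent random undersampling.

The default protocol retains the central half of the phase-encode lines
(twofold truncation) and randomly samples one sixth of that band per frame
(sixfold undersampling), a nominal 12-fold acceleration.  A few central
calibration lines are sampled in every frame so the DC energy is always
acquired; the random lines are redrawn independently per frame, which makes
the aliasing temporally incoherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SamplingPlan:
    """Per-frame boolean masks over the phase-encode index, centered k-space
    convention (DC at index ``n // 2``)."""

    n: int  # PE matrix size
    truncation: int  # outer-band truncation factor T
    undersampling: int  # random undersampling factor R within the band
    frames: int
    seed: int
    center_lines: int
    band: tuple[int, int]  # [lo, hi) retained PE index range
    masks: np.ndarray  # (frames, n) bool

    @property
    def band_width(self) -> int:
        return self.band[1] - self.band[0]

    @property
    def lines_per_frame(self) -> int:
        return int(self.masks[0].sum())


def band_range(n: int, truncation: int) -> tuple[int, int]:
    """Retained central PE band of ceil(n / T) lines, centered on DC."""
    width = -(-n // truncation)
    lo = n // 2 - width // 2
    return lo, lo + width


def _center_range(n: int, center_lines: int) -> tuple[int, int]:
    lo = n // 2 - center_lines // 2
    return lo, lo + center_lines


def make_sampling_plan(n: int, truncation: int = 2, undersampling: int = 6,
                       frames: int = 1, seed: int = 0,
                       center_lines: int = 4) -> SamplingPlan:
    """Draw the seeded per-frame masks.

    Each frame samples ``max(center_lines, round_half_up(band / R))`` lines:
    the calibration lines plus uniformly random band lines drawn without
    replacement, independently per frame.
    """
    if n < 8:
        raise ValueError("PE matrix too small")
    if truncation < 1 or undersampling < 1:
        raise ValueError("factors must be >= 1")
    lo, hi = band_range(n, truncation)
    width = hi - lo
    if undersampling > width:
        raise ValueError("undersampling factor exceeds the retained band width")
    if not 1 <= center_lines <= width:
        raise ValueError("center_lines must lie within the retained band")

    per_frame = max(center_lines, int(np.floor(width / undersampling + 0.5)))
    clo, chi = _center_range(n, center_lines)
    pool = np.array([i for i in range(lo, hi) if not clo <= i < chi])
    n_random = per_frame - center_lines

    rng = np.random.default_rng(seed)
    masks = np.zeros((frames, n), dtype=bool)
    for f in range(frames):
        masks[f, clo:chi] = True
        if n_random > 0:
            picks = rng.choice(pool, size=n_random, replace=False)
            masks[f, picks] = True
    return SamplingPlan(n=n, truncation=truncation, undersampling=undersampling,
                        frames=frames, seed=seed, center_lines=center_lines,
                        band=(lo, hi), masks=masks)


def full_sampling_plan(n: int, frames: int = 1) -> SamplingPlan:
    """Identity plan: every PE line of every frame sampled."""
    return make_sampling_plan(n, 1, 1, frames=frames, seed=0, center_lines=1)


def nominal_acceleration(plan: SamplingPlan) -> int:
    """The protocol's acceleration accounting: truncation x undersampling."""
    return plan.truncation * plan.undersampling


def empirical_sampled_fraction(plan: SamplingPlan, within_band: bool = False) -> float:
    """Mean fraction of (band) PE lines actually sampled per frame; the
    empirical acceleration is its reciprocal."""
    denom = plan.band_width if within_band else plan.n
    return float(plan.masks.sum(axis=1).mean() / denom)
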