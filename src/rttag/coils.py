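"""Simulated receive-coil sensitivity maps.

Coils are modelled as smooth complex Gaussian reception profiles centred on
a ring just outside the field of view, with a linear phase roll — a standard
stand-in for a cardiac array.  Maps are normalized so the root-sum-of-squares
is 1 inside the FOV, making multi-coil and single-coil signal levels
comparable.
"""

from __future__ import annotations

import numpy as np


def make_coil_sensitivities(n: int, n_coils: int = 8,
                            fov_fraction: float = 0.55,
                            width_fraction: float = 0.7) -> np.ndarray:
    """Complex sensitivity maps of shape (n_coils, n, n); RSS = 1."""
    if n_coils < 1:
        raise ValueError("need at least one coil")
    if n_coils == 1:
        return np.ones((1, n, n), dtype=complex)
    ax = np.arange(n) - n / 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r_ring = n * fov_fraction
    sigma = n * width_fraction / 2
    maps = np.empty((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        th = 2 * np.pi * c / n_coils
        cy, cx = r_ring * np.sin(th), r_ring * np.cos(th)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        amp = np.exp(-d2 / (2 * sigma**2))
        phase = 2 * np.pi * (yy * np.sin(th) + xx * np.cos(th)) / (4 * n)
        maps[c] = amp * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / rss
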