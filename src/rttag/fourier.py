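"""Centered, orthonormal Fourier transforms used throughout the toolkit.

k-space arrays are stored in the *centered* convention: the DC coefficient
sits at index ``N // 2`` along each axis, matching how sampling masks and
phase-encode bands are indexed.
"""

from __future__ import annotations

import numpy as np


def fft2c(x: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    """Image -> centered k-space, unitary normalisation."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(k: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    """Centered k-space -> image, unitary normalisation."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def fft1c(x: np.ndarray, axis: int) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def ifft1c(k: np.ndarray, axis: int) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(k, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )
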