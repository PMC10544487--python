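"""Image reconstruction from undersampled Cartesian k-space.

Three stages mirror the acquisition design: a zero-filled baseline, an
iterative wavelet-regularized compressed-sensing solve on the truncated
phase-encode band, and a resolution-enhancement step that restores the full
phase-encode matrix (symmetric spectral zero-padding, optionally followed by
a small learned deblurring model trained on phantom pairs).

The CS problem per frame is

    min_x  1/2 || M F x - y ||_2^2  +  lambda || Psi_d x ||_1

with ``M`` the sampling mask, ``F`` the unitary 2-D Fourier transform and
``Psi_d`` the detail coefficients of an orthogonal Daubechies-4 wavelet.
It is solved with a monotone FISTA (objective never increases past the
momentum warm-up); the objective trace is recorded per frame.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pywt

from .fourier import fft2c, ifft2c
from .sampling import SamplingPlan, band_range
from .sequence import KSpaceSeries

#: Default relative regularization weight, chosen by the packaged
#: calibration sweep on the seeded static tagged phantom fixture
#: (scripts/calibrate_lambda.py, RMSE-minimizing vs the fully sampled
#: reference); lambda_abs = lam * max|y|.
DEFAULT_CS_LAMBDA = 1e-3

_WAVELET = "db4"
_LEVELS = 3


@dataclass
class ImageSeries:
    """Reconstructed image frames with geometry and provenance."""

    data: np.ndarray  # (frames, ny, nx) complex
    pixel_spacing: tuple[float, float]  # mm (row, col)
    frame_times: np.ndarray
    provenance: str  # zero-filled | cs | cs+zeropad | cs+enhanced | reference
    pe_axis: int = 0
    fov: float = 0.0
    objective_traces: list | None = None
    converged: bool = True

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def _check_dims(kspace: KSpaceSeries, plan: SamplingPlan) -> None:
    if kspace.matrix != plan.n or kspace.mask.shape != plan.masks.shape:
        raise ValueError("k-space dimensions do not match the sampling plan")


def zero_filled_recon(kspace: KSpaceSeries, plan: SamplingPlan) -> ImageSeries:
    """Inverse transform with unsampled entries left at zero.

    Multi-coil data is combined with the sensitivity-map adjoint
    (sum of conj(S_c) * image_c; maps are RSS-normalized)."""
    _check_dims(kspace, plan)
    imgs = ifft2c(kspace.data)
    if kspace.coil_maps is not None:
        imgs = (np.conj(kspace.coil_maps)[None] * imgs).sum(axis=1)
    dx = kspace.fov / kspace.matrix
    return ImageSeries(data=imgs, pixel_spacing=(dx, dx),
                       frame_times=kspace.frame_times.copy(),
                       provenance="zero-filled", pe_axis=kspace.pe_axis,
                       fov=kspace.fov)


def _wavelet_split(x: np.ndarray):
    level = min(_LEVELS, pywt.dwtn_max_level(x.shape, _WAVELET))
    coeffs = pywt.wavedec2(x, _WAVELET, mode="periodization", level=max(level, 1))
    arr, slices = pywt.coeffs_to_array(coeffs)
    return arr, slices


def _wavelet_merge(arr, slices):
    coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec2")
    return pywt.waverec2(coeffs, _WAVELET, mode="periodization")


def _soft_threshold_details(x: np.ndarray, thresh: float) -> np.ndarray:
    """Proximal step of ``thresh * || Psi_d x ||_1`` for an orthogonal
    wavelet: complex soft-thresholding of the detail coefficients."""
    re, sl = _wavelet_split(x.real)
    im, _ = _wavelet_split(x.imag)
    arr = re + 1j * im
    mag = np.abs(arr)
    shrink = np.maximum(1 - thresh / np.maximum(mag, 1e-30), 0.0)
    out = arr * shrink
    a_sl = sl[0]  # approximation band: not penalized
    out[a_sl] = arr[a_sl]
    return _wavelet_merge(out.real, sl) + 1j * _wavelet_merge(out.imag, sl)


def _l1_details(x: np.ndarray) -> float:
    re, sl = _wavelet_split(x.real)
    im, _ = _wavelet_split(x.imag)
    arr = re + 1j * im
    a_sl = sl[0]
    total = np.abs(arr).sum() - np.abs(arr[a_sl]).sum()
    return float(total)


def _crop_band(kspace: KSpaceSeries, plan: SamplingPlan):
    """Restrict k-space and masks to the retained PE band."""
    lo, hi = plan.band
    if kspace.pe_axis == 0:
        data = kspace.data[..., lo:hi, :]
    else:
        data = kspace.data[..., :, lo:hi]
    return data, plan.masks[:, lo:hi]


def _lowres_maps(maps: np.ndarray, band_w: int, pe_axis: int) -> np.ndarray:
    """Coil sensitivities resampled onto the truncated-band image grid."""
    axis = 1 + pe_axis
    n = maps.shape[axis]
    k = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(maps, axes=axis),
                                   axis=axis, norm="ortho"), axes=axis)
    start = n // 2 - band_w // 2
    sl = [slice(None)] * maps.ndim
    sl[axis] = slice(start, start + band_w)
    low = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(k[tuple(sl)], axes=axis),
                                      axis=axis, norm="ortho"), axes=axis)
    rss = np.sqrt((np.abs(low) ** 2).sum(axis=0))
    return low / np.maximum(rss, 1e-12)


def cs_recon(kspace: KSpaceSeries, plan: SamplingPlan,
             lam: float = DEFAULT_CS_LAMBDA, iterations: int = 60,
             tolerance: float = 1e-6, temporal: bool = False) -> ImageSeries:
    """Compressed-sensing solve on the truncated-band grid.

    ``lam`` is relative to the peak sampled k-space magnitude of each frame;
    the output grid is the acquired resolution (coarser pixels along PE when
    the plan truncates).  Monotone FISTA; a frame that fails to reach the
    relative-change tolerance sets ``converged=False`` on the series.

    ``temporal=True`` switches from per-frame spatial-wavelet sparsity to
    joint temporal-Fourier (x-f) sparsity across the whole frame stack,
    which exploits the frame-to-frame incoherence of the random masks.
    """
    _check_dims(kspace, plan)
    if lam < 0 or iterations < 1:
        raise ValueError("need lam >= 0 and iterations >= 1")
    kdata, masks = _crop_band(kspace, plan)
    pe_axis = kspace.pe_axis
    n_frames = kdata.shape[0]
    out = np.zeros_like(kdata)
    traces: list[list[float]] = []
    all_ok = True

    if temporal:
        if kspace.coil_maps is not None:
            raise ValueError("temporal joint solve supports single-coil data only")
        out, trace, all_ok = _cs_temporal(kdata, masks, pe_axis, lam,
                                          iterations, tolerance)
        traces = [trace]
        dx = kspace.fov / kspace.matrix
        band_w = kdata.shape[1 + pe_axis]
        d_pe = kspace.fov / band_w
        spacing = (d_pe, dx) if pe_axis == 0 else (dx, d_pe)
        return ImageSeries(data=out, pixel_spacing=spacing,
                           frame_times=kspace.frame_times.copy(),
                           provenance="cs", pe_axis=pe_axis, fov=kspace.fov,
                           objective_traces=traces, converged=all_ok)

    smaps = None
    if kspace.coil_maps is not None:
        band_w = kdata.shape[-1 if pe_axis == 1 else -2]
        smaps = _lowres_maps(kspace.coil_maps, band_w, pe_axis)
        out = np.zeros(kdata.shape[:1] + kdata.shape[2:], dtype=complex)

    for f in range(n_frames):
        y = kdata[f]
        m = masks[f]
        msel = np.zeros(y.shape[-2:], dtype=bool)
        if pe_axis == 0:
            msel[m, :] = True
        else:
            msel[:, m] = True
        lam_abs = lam * (np.abs(y).max() or 1.0)

        if smaps is None:
            def A(xx):
                return np.where(msel, fft2c(xx), 0)

            def AH(kk):
                return ifft2c(kk)
        else:
            def A(xx):
                return np.where(msel[None], fft2c(smaps * xx[None]), 0)

            def AH(kk):
                return (np.conj(smaps) * ifft2c(kk)).sum(axis=0)

        x = AH(y)  # zero-filled / adjoint start
        if lam == 0 and msel.all() and smaps is None:
            out[f] = x
            traces.append([0.0])
            continue

        def objective(xx):
            r = A(xx) - y
            return 0.5 * np.vdot(r, r).real + lam_abs * _l1_details(xx)

        z = x.copy()
        t_mom = 1.0
        fx = objective(x)
        trace = [fx]
        ok = False
        for _ in range(iterations):
            grad = AH(A(z) - y)
            x_new = _soft_threshold_details(z - grad, lam_abs)
            f_new = objective(x_new)
            if f_new > fx:  # monotone step: fall back to gradient from x
                x_new = _soft_threshold_details(x - AH(A(x) - y), lam_abs)
                f_new = objective(x_new)
                if f_new > fx:
                    x_new, f_new = x, fx
            t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
            z = x_new + (t_mom - 1) / t_new * (x_new - x)
            rel = np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-30)
            x, fx, t_mom = x_new, f_new, t_new
            trace.append(fx)
            if rel < tolerance:
                ok = True
                break
        traces.append(trace)
        all_ok = all_ok and ok
        out[f] = x

    dx = kspace.fov / kspace.matrix
    band_w = kdata.shape[-1 if pe_axis == 1 else -2]
    d_pe = kspace.fov / band_w
    spacing = (d_pe, dx) if pe_axis == 0 else (dx, d_pe)
    return ImageSeries(data=out, pixel_spacing=spacing,
                       frame_times=kspace.frame_times.copy(), provenance="cs",
                       pe_axis=pe_axis, fov=kspace.fov,
                       objective_traces=traces, converged=all_ok)


def _cs_temporal(kdata, masks, pe_axis, lam, iterations, tolerance):
    """Joint x-f solve: soft-thresholding in the temporal-Fourier domain."""
    msel = np.zeros(kdata.shape, dtype=bool)
    for f in range(kdata.shape[0]):
        if pe_axis == 0:
            msel[f, masks[f], :] = True
        else:
            msel[f, :, masks[f]] = True
    y = kdata
    lam_abs = lam * (np.abs(y).max() or 1.0)

    def ft(x):
        return np.fft.fft(x, axis=0, norm="ortho")

    def ift(x):
        return np.fft.ifft(x, axis=0, norm="ortho")

    def prox(x, t):
        c = ft(x)
        mag = np.abs(c)
        c *= np.maximum(1 - t / np.maximum(mag, 1e-30), 0.0)
        return ift(c)

    def objective(x):
        r = np.where(msel, fft2c(x), 0) - y
        return 0.5 * np.vdot(r, r).real + lam_abs * np.abs(ft(x)).sum()

    x = ifft2c(y)
    z = x.copy()
    t_mom = 1.0
    fx = objective(x)
    trace = [fx]
    ok = False
    for _ in range(iterations):
        grad = ifft2c(np.where(msel, fft2c(z), 0) - y)
        x_new = prox(z - grad, lam_abs)
        f_new = objective(x_new)
        if f_new > fx:
            x_new = prox(x - ifft2c(np.where(msel, fft2c(x), 0) - y), lam_abs)
            f_new = objective(x_new)
            if f_new > fx:
                x_new, f_new = x, fx
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        z = x_new + (t_mom - 1) / t_new * (x_new - x)
        rel = np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1e-30)
        x, fx, t_mom = x_new, f_new, t_new
        trace.append(fx)
        if rel < tolerance:
            ok = True
            break
    return x, trace, ok


def zero_pad_enhance(series: ImageSeries, full_matrix: int) -> ImageSeries:
    """Restore the full PE matrix by symmetric spectral zero-padding.

    The acquired low-frequency coefficients are preserved exactly (so
    truncating back is the identity); under the orthonormal transform
    convention the overall image amplitude scales by sqrt(band/full).
    """
    axis = 1 + series.pe_axis
    n_in = series.data.shape[axis]
    if n_in > full_matrix:
        raise ValueError("target matrix smaller than the input")
    if n_in == full_matrix:
        padded = series.data.copy()
    else:
        k = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(series.data, axes=axis),
                                       axis=axis, norm="ortho"), axes=axis)
        lo, _ = band_range(full_matrix, 1)
        shape = list(series.data.shape)
        shape[axis] = full_matrix
        kfull = np.zeros(shape, dtype=complex)
        start = full_matrix // 2 - n_in // 2
        sl = [slice(None)] * k.ndim
        sl[axis] = slice(start, start + n_in)
        kfull[tuple(sl)] = k
        padded = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(kfull, axes=axis),
                                             axis=axis, norm="ortho"), axes=axis)
    d_new = series.fov / full_matrix if series.fov else series.pixel_spacing[series.pe_axis] * n_in / full_matrix
    spacing = list(series.pixel_spacing)
    spacing[series.pe_axis] = d_new
    prov = "cs+zeropad" if series.provenance.startswith("cs") else series.provenance + "+zeropad"
    return ImageSeries(data=padded, pixel_spacing=tuple(spacing),
                       frame_times=series.frame_times.copy(), provenance=prov,
                       pe_axis=series.pe_axis, fov=series.fov)


def truncate_pe(series: ImageSeries, band_matrix: int) -> ImageSeries:
    """Inverse of ``zero_pad_enhance``: crop the PE spectrum to a band."""
    axis = 1 + series.pe_axis
    n_in = series.data.shape[axis]
    if band_matrix > n_in:
        raise ValueError("band larger than the input")
    k = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(series.data, axes=axis),
                                   axis=axis, norm="ortho"), axes=axis)
    start = n_in // 2 - band_matrix // 2
    sl = [slice(None)] * k.ndim
    sl[axis] = slice(start, start + band_matrix)
    cropped = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(k[tuple(sl)], axes=axis),
                                          axis=axis, norm="ortho"), axes=axis)
    spacing = list(series.pixel_spacing)
    spacing[series.pe_axis] = spacing[series.pe_axis] * n_in / band_matrix
    return ImageSeries(data=cropped, pixel_spacing=tuple(spacing),
                       frame_times=series.frame_times.copy(),
                       provenance=series.provenance, pe_axis=series.pe_axis,
                       fov=series.fov)


# ---------------------------------------------------------------------------
# Learned resolution enhancer: a small convolutional residual model trained
# by plain gradient descent on phantom image pairs.  It is a desk-scale
# stand-in for a full deep-learning deblurring network: a single linear
# convolution kernel (initialized to the identity) learns to sharpen the
# zero-padded low-resolution input toward the full-resolution reference.
# ---------------------------------------------------------------------------


@dataclass
class EnhancerConfig:
    epochs: int = 200
    kernel_shape: tuple[int, int] = (11, 5)  # (PE, readout) extent
    learning_rate: float = 1.0  # relative to the tap-autocorrelation bound
    loss: str = "l2"
    seed: int = 0


@dataclass
class EnhancerModel:
    kernel: np.ndarray  # real 2-D convolution kernel, PE axis first
    config: EnhancerConfig
    matrix: int  # expected square input size
    pe_axis: int = 0

    def params_hash(self) -> str:
        return hashlib.sha256(self.kernel.tobytes()).hexdigest()


def _conv2_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Linear 'same' convolution via the FFT (circular boundary)."""
    ky, kx = kernel.shape
    n0, n1 = x.shape[-2:]
    kpad = np.zeros((n0, n1))
    kpad[:ky, :kx] = kernel
    kpad = np.roll(kpad, (-(ky // 2), -(kx // 2)), axis=(0, 1))
    kf = np.fft.fft2(kpad)
    return np.fft.ifft2(np.fft.fft2(x, axes=(-2, -1)) * kf, axes=(-2, -1))


def synthesize_enhancer_pairs(reference: ImageSeries,
                              band_matrix: int) -> tuple[ImageSeries, ImageSeries]:
    """Build a training pair from a full-resolution reference series: the
    input is the reference PE-truncated to ``band_matrix`` lines and
    zero-padded back (the same blur the accelerated acquisition suffers)."""
    n_full = reference.data.shape[1 + reference.pe_axis]
    blurred = zero_pad_enhance(truncate_pe(reference, band_matrix), n_full)
    return reference, blurred


def train_enhancer(pairs: list[tuple[ImageSeries, ImageSeries]],
                   config: EnhancerConfig | None = None) -> EnhancerModel:
    """Fit the enhancer on (reference, zero-padded low-resolution) pairs.

    Frames are magnitude-normalized; the kernel starts as the identity, so
    zero epochs yield an identity model.  Gradient descent on the L2 loss is
    fully deterministic for a given seed and config.
    """
    config = config or EnhancerConfig()
    if not pairs:
        raise ValueError("need at least one training pair")
    refs, ins = [], []
    for ref, lo in pairs:
        if ref.shape != lo.shape:
            raise ValueError("pair geometry mismatch")
        for a, b in zip(np.abs(ref.data), np.abs(lo.data)):
            s = b.max() or 1.0
            refs.append(a / s)
            ins.append(b / s)
    X = np.stack(ins)
    Y = np.stack(refs)
    ky, kx = config.kernel_shape
    if pairs[0][0].pe_axis == 1:
        ky, kx = kx, ky
    kernel = np.zeros((ky, kx))
    kernel[ky // 2, kx // 2] = 1.0  # identity init
    n_pix = X[0].size * len(X)
    # step size scaled by the tap-autocorrelation Lipschitz bound
    lr = config.learning_rate / max(np.mean(X**2) * ky * kx, 1e-12)
    for _ in range(config.epochs):
        pred = _conv2_same(X, kernel).real
        resid = pred - Y
        # gradient of 0.5*mean(resid^2) wrt kernel taps
        grad = np.empty_like(kernel)
        for i in range(ky):
            for j in range(kx):
                shifted = np.roll(X, (i - ky // 2, j - kx // 2), axis=(-2, -1))
                grad[i, j] = np.sum(resid * shifted) / n_pix
        kernel -= lr * grad
    return EnhancerModel(kernel=kernel, config=config,
                         matrix=pairs[0][0].shape[0], pe_axis=pairs[0][0].pe_axis)


def apply_enhancer(model: EnhancerModel, series: ImageSeries) -> ImageSeries:
    """Deblur a zero-padded full-matrix series with the trained kernel."""
    if series.shape != (model.matrix, model.matrix):
        raise ValueError("series geometry does not match the enhancer contract")
    out = _conv2_same(series.data.real, model.kernel).real \
        + 1j * _conv2_same(series.data.imag, model.kernel).real
    return ImageSeries(data=out, pixel_spacing=series.pixel_spacing,
                       frame_times=series.frame_times.copy(),
                       provenance="cs+enhanced", pe_axis=series.pe_axis,
                       fov=series.fov)
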