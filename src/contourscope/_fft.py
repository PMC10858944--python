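"""Shared padded-FFT convolution machinery.

Every convolution in the package — the forward model, its adjoint, and the
Wiener inverse — goes through the helpers here so that forward and inverse
paths use bit-identical padding conventions.  Linear (aperiodic) convolution
is realized by zero-padding both operands to a common fast FFT length of at
least ``scene + kernel - 1`` per axis, multiplying spectra, and cropping the
top-left ``scene``-sized block.  With the kernel rolled so that its center
pixel ``(ky//2, kx//2)`` sits at the origin, that crop equals the usual
"same"-sized linear convolution, and the top-left crop is exactly the adjoint
of the top-left zero-pad, so correlation with the conjugate spectrum is the
exact adjoint of the forward map.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _spfft

__all__ = [
    "padded_shape",
    "kernel_spectrum",
    "conv_same",
    "corr_same",
    "wiener_apply",
]


def padded_shape(scene_shape, kernel_shape):
    """Fast FFT lengths covering linear convolution of the two shapes."""
    return tuple(
        _spfft.next_fast_len(s + k - 1) for s, k in zip(scene_shape, kernel_shape)
    )


def kernel_spectrum(kernel, pshape, dtype=np.float64):
    """rFFT of ``kernel`` zero-embedded in ``pshape`` with its center at (0,0)."""
    ky, kx = kernel.shape
    buf = np.zeros(pshape, dtype=dtype)
    buf[:ky, :kx] = kernel
    buf = np.roll(buf, (-(ky // 2), -(kx // 2)), axis=(0, 1))
    return _spfft.rfft2(buf)


def _pad_topleft(arr, pshape):
    out = np.zeros(arr.shape[:-2] + tuple(pshape), dtype=arr.dtype)
    out[..., : arr.shape[-2], : arr.shape[-1]] = arr
    return out


def conv_same(scene, kspec, pshape, out_shape=None):
    """Linear convolution with a precomputed kernel spectrum, "same" crop.

    ``scene`` may carry leading batch axes; the transform acts on the last two.
    """
    if out_shape is None:
        out_shape = scene.shape[-2:]
    spec = _spfft.rfft2(_pad_topleft(scene, pshape))
    full = _spfft.irfft2(spec * kspec, s=pshape)
    return full[..., : out_shape[0], : out_shape[1]]


def corr_same(scene, kspec, pshape, out_shape=None):
    """Adjoint of :func:`conv_same` (correlation with the same kernel)."""
    if out_shape is None:
        out_shape = scene.shape[-2:]
    spec = _spfft.rfft2(_pad_topleft(scene, pshape))
    full = _spfft.irfft2(spec * np.conj(kspec), s=pshape)
    return full[..., : out_shape[0], : out_shape[1]]


def wiener_apply(b, kspec, gamma, pshape):
    """Apply the Tikhonov-regularized inverse filter on the padded grid.

    Computes ``conj(K)·F(b) / (|K|² + γ)`` on the zero-padded grid and crops
    back to the shape of ``b``.
    """
    denom = np.abs(kspec) ** 2 + gamma
    spec = _spfft.rfft2(_pad_topleft(b, pshape))
    full = _spfft.irfft2(np.conj(kspec) * spec / denom, s=pshape)
    return full[..., : b.shape[-2], : b.shape[-1]]
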