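"""Centered FFT helpers shared by the forward model and the reconstruction engine.

All spectra in this package are "centered": the zero-frequency sample sits at
index ``side // 2`` along every axis, matching the real-space convention that
the particle/volume origin is the voxel at index ``box // 2`` (0-based).
"""

from __future__ import annotations

import numpy as np


def fftn_center(a: np.ndarray) -> np.ndarray:
    """N-dimensional DFT with the origin of both domains at ``side // 2``."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def ifftn_center(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a)))


def fft2_center(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a, axes=(-2, -1))), axes=(-2, -1))


def ifft2_center(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a, axes=(-2, -1))), axes=(-2, -1))


def pad_center(a: np.ndarray, side: int) -> np.ndarray:
    """Embed ``a`` (cubic or square) into a zero array of the given side.

    Centers are aligned: old index ``n // 2`` maps to new index ``side // 2``.
    """
    n = a.shape[-1]
    if side < n:
        raise ValueError("pad side smaller than input")
    out = np.zeros(a.shape[:-a.ndim] + (side,) * a.ndim, dtype=a.dtype)
    lo = side // 2 - n // 2
    sl = tuple(slice(lo, lo + n) for _ in range(a.ndim))
    out[sl] = a
    return out


def crop_center(a: np.ndarray, side: int) -> np.ndarray:
    """Inverse of :func:`pad_center`."""
    n = a.shape[-1]
    if side > n:
        raise ValueError("crop side larger than input")
    lo = n // 2 - side // 2
    sl = tuple(slice(lo, lo + side) for _ in range(a.ndim))
    return a[sl]


def freq_grid_2d(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered integer frequency indices (qx, qy) for a square image."""
    q = np.arange(side) - side // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")
    return qx, qy


def shift_phase_2d(side: int, shift_x: float, shift_y: float) -> np.ndarray:
    """Phase ramp that translates an image by (+shift_x, +shift_y) pixels."""
    qx, qy = freq_grid_2d(side)
    return np.exp(-2j * np.pi * (qx * shift_x + qy * shift_y) / side)


def radial_shell_index(shape: tuple[int, ...]) -> np.ndarray:
    """Integer-rounded radius of every sample from the centered origin."""
    side = shape[-1]
    q = np.arange(side) - side // 2
    if len(shape) == 2:
        qx, qy = np.meshgrid(q, q, indexing="xy")
        r = np.sqrt(qx**2 + qy**2)
    elif len(shape) == 3:
        qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
        r = np.sqrt(qx**2 + qy**2 + qz**2)
    else:
        raise ValueError("only 2-D or 3-D shapes supported")
    return np.rint(r).astype(np.int64)
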