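"""Centered, unitary FFT helpers.

Convention used throughout the package: the DC sample of an ``n``-point
k-space axis sits at 0-based index ``n // 2`` (1-based grid line
``n // 2 + 1``), and all transforms are unitary (``norm="ortho"``), so
Parseval holds without scale factors between image and k-space.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _sfft


def fftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered unitary forward FFT along one axis."""
    return _sfft.fftshift(
        _sfft.fft(_sfft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def ifftc(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered unitary inverse FFT along one axis."""
    return _sfft.fftshift(
        _sfft.ifft(_sfft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2D forward FFT (image -> k-space) over ``axes``."""
    return _sfft.fftshift(
        _sfft.fft2(_sfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2D inverse FFT (k-space -> image) over ``axes``."""
    return _sfft.fftshift(
        _sfft.ifft2(_sfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )
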