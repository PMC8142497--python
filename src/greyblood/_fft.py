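"""Centered, unitary FFT helpers.

Convention used throughout the package: the DC sample sits at index
``N // 2`` on every axis and all transforms are orthonormal, so k-space and
image-domain L2 norms are identical to machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fftc", "ifftc", "centered_indices", "phase_ramp"]


def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary forward FFT over ``axes`` (all axes by default)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary inverse FFT over ``axes`` (all axes by default)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def centered_indices(n: int) -> np.ndarray:
    """Integer k-space indices with DC at position ``n // 2``."""
    return np.arange(n) - n // 2


def phase_ramp(n: int, shift: float) -> np.ndarray:
    """1D k-space phase ramp that translates an image by ``shift`` pixels.

    Multiplying the centered k-space of an image by this ramp moves image
    content by ``+shift`` samples (circularly) along that axis.
    """
    k = centered_indices(n)
    return np.exp(-2j * np.pi * k * shift / n)
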