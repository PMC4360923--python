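"""Rician noise model: squared-magnitude transform and background-based σ.

A single-coil magnitude image |z| = sqrt((r + n1)² + n2²) with
n1, n2 ~ N(0, σ²) is Rician.  Its squared magnitude has the
signal-independent expectation E|z|² = r² + 2σ², so in a zero-signal
background E|z|² = 2σ², which yields the estimator σ = sqrt(μ/2) with μ
the background mean of the squared image.  Denoising in the squared
domain therefore needs only the constant bias 2σ² removed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Mask, Volume, check_same_shape

__all__ = ["NoiseEstimate", "squared_magnitude", "estimate_sigma", "unbias_squared"]


@dataclass(frozen=True)
class NoiseEstimate:
    """σ and the background statistics it was derived from."""

    sigma: float
    background_mean: float
    n_background: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_background < 1:
            raise ValueError("at least one background voxel required")


def squared_magnitude(v: Volume) -> Volume:
    """Elementwise square of a magnitude image.

    Magnitude images are non-negative; negative inputs are rejected.
    """
    if np.any(v.data < 0):
        raise ValueError("magnitude image has negative values")
    return v.with_data(v.data ** 2)


def estimate_sigma(squared: Volume, background: Mask) -> NoiseEstimate:
    """Estimate σ from the squared magnitude over the background region.

    σ = sqrt(μ / 2) where μ is the arithmetic mean of the squared
    magnitude over the background mask (E|z|² = 2σ² where the true
    signal is zero).  Only background voxels are read.
    """
    check_same_shape(squared, background)
    n = int(background.data.sum())
    if n == 0:
        raise ValueError("empty background mask")
    mu = float(squared.data[background.data].mean())
    return NoiseEstimate(sigma=float(np.sqrt(mu / 2.0)), background_mean=mu, n_background=n)


def unbias_squared(denoised_squared: Volume, sigma: float) -> Volume:
    """Remove the 2σ² Rician bias and return to the magnitude domain.

    Computes sqrt(max(x − 2σ², 0)) elementwise.  Values driven negative
    by the subtraction are clamped to zero before the square root
    (magnitudes are non-negative).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    shifted = denoised_squared.data - 2.0 * sigma ** 2
    return denoised_squared.with_data(np.sqrt(np.clip(shifted, 0.0, None)))
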