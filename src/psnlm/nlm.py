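"""3D non-local means and its pre-smoothed-weights variant.

Each output voxel is a weighted average of the voxels in a search window
centred on it, with weights

    w(p, q) = exp(−‖patch(p) − patch(q)‖²_{G_a} / h²) / Z(p),

where the patch distance is a Gaussian-weighted (G_a, normalized to sum
to 1 over the patch) sum of squared differences between the two patches
and h is the filtering degree, in the intensity units of the volume the
distances are computed on.  The pre-smoothed variant computes the
distances (hence w and Z) on a separate guidance volume while averaging
the intensities of the volume being filtered; with guide == input it is
exactly plain NLM.

Conventions (all mirrored by the brute-force oracle in the test suite):
the centre voxel's weight uses its literal (zero) patch distance;
patches at volume borders use reflective padding (numpy ``reflect``, no
edge repeat); search windows are clipped at volume borders and the
weights renormalized, so the output is a convex combination everywhere.

The implementation loops over search-window *offsets* rather than
voxels: for each offset d the patch distances of every voxel to its
d-neighbour are obtained with one shifted squared difference and a
separable correlation with the G_a kernel, giving O(|search| · N) work
with vectorized inner loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.ndimage import correlate1d

from .volume import Volume, check_same_shape

__all__ = ["NLMParams", "nlm_denoise", "psnlm_denoise"]


@dataclass(frozen=True)
class NLMParams:
    """Patch/search geometry and filtering degree.

    h is expressed in the intensity units of the volume the weights are
    computed from (after a variance-stabilizing transform the noise std
    is 1, so h is O(1) there).  h=None defers the choice to the pipeline,
    which scales it from the noise level of the filtered domain; the
    filters themselves require a concrete positive h.
    """

    h: float | None = None
    patch_size: int = 5
    search_size: int = 11
    patch_gaussian_a: float = 1.0

    def __post_init__(self) -> None:
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be positive")
        if self.patch_size % 2 == 0 or self.search_size % 2 == 0:
            raise ValueError("patch_size and search_size must be odd")
        if self.patch_size < 1 or self.patch_size > self.search_size:
            raise ValueError("need 1 <= patch_size <= search_size")
        if self.patch_gaussian_a <= 0:
            raise ValueError("patch_gaussian_a must be positive")


def _patch_kernel_1d(params: NLMParams) -> np.ndarray:
    ph = params.patch_size // 2
    o = np.arange(-ph, ph + 1, dtype=np.float64)
    k = np.exp(-(o ** 2) / (2.0 * params.patch_gaussian_a ** 2))
    return k / k.sum()  # product of normalized 1D kernels => normalized 3D G_a


def _nlm_core(values: np.ndarray, guide: np.ndarray, params: NLMParams) -> np.ndarray:
    if params.h is None:
        raise ValueError("h must be set (a positive filtering degree)")
    shape = values.shape
    ph = params.patch_size // 2
    sh = params.search_size // 2
    k1 = _patch_kernel_1d(params)
    gp = np.pad(guide, ph, mode="reflect") if ph else guide
    inv_h2 = 1.0 / params.h ** 2

    num = np.zeros(shape, dtype=np.float64)
    den = np.zeros(shape, dtype=np.float64)
    for d in product(range(-sh, sh + 1), repeat=3):
        # voxels x for which the candidate x + d lies inside the volume
        a0 = [max(0, -di) for di in d]
        a1 = [shape[i] - max(0, d[i]) for i in range(3)]
        if any(a1[i] <= a0[i] for i in range(3)):
            continue
        # squared guide difference on the padded overlap, then G_a-correlate;
        # the [ph : ph + (a1-a0)] central slice is fully interior to the overlap
        base = tuple(slice(a0[i], a1[i] + 2 * ph) for i in range(3))
        shifted = tuple(slice(a0[i] + d[i], a1[i] + d[i] + 2 * ph) for i in range(3))
        diff2 = gp[base] - gp[shifted]
        np.square(diff2, out=diff2)
        for axis in range(3):
            diff2 = correlate1d(diff2, k1, axis=axis, mode="constant")
        dsq = diff2[tuple(slice(ph, ph + a1[i] - a0[i]) for i in range(3))]

        w = np.exp(-dsq * inv_h2)
        out_sl = tuple(slice(a0[i], a1[i]) for i in range(3))
        val_sl = tuple(slice(a0[i] + d[i], a1[i] + d[i]) for i in range(3))
        num[out_sl] += w * values[val_sl]
        den[out_sl] += w
    return num / den


def nlm_denoise(noisy: Volume, params: NLMParams) -> Volume:
    """Plain 3D non-local means: weights and values from the same volume."""
    if min(noisy.shape) < params.patch_size:
        raise ValueError("volume extents must be >= patch_size")
    return noisy.with_data(_nlm_core(noisy.data, noisy.data, params))


def psnlm_denoise(transformed: Volume, presmoothed: Volume, params: NLMParams) -> Volume:
    """NLM with weights from a pre-smoothed guide, averaging ``transformed``.

    Identical to :func:`nlm_denoise` except patch distances (hence the
    weights and normalizing constant) are computed on ``presmoothed``.
    """
    check_same_shape(transformed, presmoothed)
    if min(transformed.shape) < params.patch_size:
        raise ValueError("volume extents must be >= patch_size")
    return transformed.with_data(_nlm_core(transformed.data, presmoothed.data, params))
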