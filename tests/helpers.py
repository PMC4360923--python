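"""Independent oracles shared by the test suite.

These implement the *definitions* directly (explicit loops over voxels,
patches and histogram cuts) and are deliberately independent of the
package's vectorized implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from psnlm.nlm import NLMParams


def patch_weight_kernel(params: NLMParams) -> np.ndarray:
    """The normalized 3D Gaussian patch-weighting kernel G_a."""
    ph = params.patch_size // 2
    o = np.arange(-ph, ph + 1, dtype=float)
    k1 = np.exp(-(o ** 2) / (2.0 * params.patch_gaussian_a ** 2))
    k = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    return k / k.sum()


def nlm_brute_force(values: np.ndarray, guide: np.ndarray, params: NLMParams) -> np.ndarray:
    """Definitional NLM: per-voxel loop over the (clipped) search window.

    Patch distances are G_a-weighted sums of squared differences between
    reflect-padded patches of ``guide``; averaged intensities come from
    ``values``.  Patches are gathered per voxel; the candidate loop is
    vectorized over the search window only through plain array indexing.
    """
    ph, sh = params.patch_size // 2, params.search_size // 2
    kernel = patch_weight_kernel(params).ravel()
    gp = np.pad(guide, ph, mode="reflect") if ph else guide
    shape = values.shape

    # every voxel's patch, flattened: index [i, j, k] -> patch vector
    from numpy.lib.stride_tricks import sliding_window_view
    patches = sliding_window_view(gp, (2 * ph + 1,) * 3).reshape(*shape, -1)

    out = np.zeros(shape)
    for i, j, k in product(*(range(s) for s in shape)):
        p = patches[i, j, k]
        num = den = 0.0
        for di, dj, dk in product(range(-sh, sh + 1), repeat=3):
            l, m, n = i + di, j + dj, k + dk
            if not (0 <= l < shape[0] and 0 <= m < shape[1] and 0 <= n < shape[2]):
                continue
            d2 = float(np.dot(kernel, (p - patches[l, m, n]) ** 2))
            w = np.exp(-d2 / params.h ** 2)
            num += w * values[l, m, n]
            den += w
        out[i, j, k] = num / den
    return out


def nlm_brute_force_pairs(values: np.ndarray, guide: np.ndarray, params: NLMParams) -> np.ndarray:
    """Definitional NLM for a search window covering the whole image.

    Enumerates *all pairs* of voxels: the full patch-distance matrix is
    built explicitly from reflect-padded patches and the weighted average
    taken per row.  Valid only when the search window reaches every voxel
    from every voxel (search_size >= 2*max(shape) - 1).
    """
    assert params.search_size >= 2 * max(values.shape) - 1
    ph = params.patch_size // 2
    kernel = patch_weight_kernel(params).ravel()
    gp = np.pad(guide, ph, mode="reflect") if ph else guide
    from numpy.lib.stride_tricks import sliding_window_view
    patches = sliding_window_view(gp, (2 * ph + 1,) * 3).reshape(values.size, -1)

    flat = values.ravel()
    out = np.empty(values.size)
    for start in range(0, values.size, 64):
        rows = patches[start:start + 64]
        d2 = ((rows[:, None, :] - patches[None, :, :]) ** 2) @ kernel
        w = np.exp(-d2 / params.h ** 2)
        out[start:start + 64] = (w @ flat) / w.sum(axis=1)
    return out.reshape(values.shape)


def otsu_brute_force(data: np.ndarray, bins: int) -> float:
    """Exhaustive between-class-variance scan over every interior bin edge."""
    counts, edges = np.histogram(data, bins=bins, range=(data.min(), data.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = None, -np.inf
    for cut in range(1, bins):  # classes: bins [0, cut) vs [cut, bins)
        w0, w1 = counts[:cut].sum(), counts[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:cut] * centers[:cut]).sum() / w0
        m1 = (counts[cut:] * centers[cut:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:  # strict: ties keep the lowest edge
            best_t, best_v = edges[cut], v
    return float(best_t)


def windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Uniform mean over a border-clipped centred cubic window."""
    from scipy.ndimage import correlate

    ones = np.ones((window,) * 3)
    num = correlate(values, ones, mode="constant")
    den = correlate(np.ones_like(values), ones, mode="constant")
    return num / den
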