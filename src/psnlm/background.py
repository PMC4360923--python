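"""Automatic background extraction for σ estimation.

A magnitude MR brain volume has an empty, near-zero background; the σ
estimator needs exactly that region.  The pipeline is: median filter →
Otsu threshold (foreground = above-threshold, the bright brain/head) →
morphological close of the foreground → fill enclosed holes → background
is the complement of the filled foreground.

Otsu's threshold is the exhaustive maximizer of between-class variance
over the candidate cuts of the intensity histogram.  It is implemented
here directly (vectorized over all bin edges) because this package pins
the conventions down: candidate thresholds are interior bin edges,
classes are split as (≤ t, > t), and ties break to the lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .volume import Mask, Volume

__all__ = ["SegmentationConfig", "otsu_threshold", "extract_background"]


@dataclass(frozen=True)
class SegmentationConfig:
    median_window: int = 3      # odd voxel extent per axis
    close_radius: int = 2       # structuring-element radius, voxels
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if self.close_radius < 0:
            raise ValueError("close_radius must be >= 0")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")


def otsu_threshold(v: Volume, bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of the intensity histogram.

    Histograms the volume into ``bins`` equal-width bins over the data
    range and evaluates every interior bin edge t as a cut into classes
    (≤ t) and (> t), using bin centers as class representatives.  Returns
    the edge with the largest between-class variance w0·w1·(m0 − m1)²;
    ties break to the lowest edge.

    Raises on a constant volume (degenerate histogram: no cut separates
    two classes).
    """
    data = v.data
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("degenerate histogram: constant volume")
    counts, edges = np.histogram(data, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)[:-1].astype(np.float64)            # class (<= edge)
    w1 = data.size - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s_total = float((counts * centers).sum())
    valid = (w0 > 0) & (w1 > 0)
    m0 = np.where(w0 > 0, s0 / np.maximum(w0, 1), 0.0)
    m1 = np.where(w1 > 0, (s_total - s0) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (m0 - m1) ** 2, -np.inf)
    best = int(np.argmax(between))  # argmax takes the first → lowest edge on ties
    return float(edges[1:-1][best])


def extract_background(v: Volume, config: SegmentationConfig | None = None) -> Mask:
    """Extract the zero-signal background of a magnitude MR volume.

    median filter → binarize at the Otsu threshold (foreground = above)
    → morphological close of the foreground with a 3D ball → fill
    enclosed holes (full 3D connectivity) → background = complement.
    """
    cfg = config or SegmentationConfig()
    med = ndimage.median_filter(v.data, size=cfg.median_window, mode="reflect")
    t = otsu_threshold(Volume(med, v.spacing), bins=cfg.histogram_bins)
    fg = med > t
    if cfg.close_radius > 0:
        fg = ndimage.binary_closing(fg, structure=ball(cfg.close_radius))
    fg = ndimage.binary_fill_holes(fg)
    return Mask(~fg)
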