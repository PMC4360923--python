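"""Brain-like synthetic phantoms and Rician noise injection.

The phantom is a piecewise-constant multi-tissue volume: a head-shaped
ellipsoid of tissue classes (assigned by thresholding a seeded smooth
random field, so class regions are blob-like with curved interfaces)
surrounded by a strictly zero background.  It is an invented stand-in
for simulated-anatomy ground truth: downstream tests and experiments
rely only on its statistical structure — piecewise-constant classes with
a known brightest-tissue intensity t and a zero background occupying at
least a quarter of the volume — not on anatomical realism.

Noise is injected exactly as in the single-coil acquisition model: two
independent zero-mean Gaussian fields of std σ = (percent/100)·t are
added to the real and imaginary channels (phase θ = 0, so the signal
lies entirely in the real channel) and the magnitude is taken:

    |z| = sqrt((r + σ·g₁)² + (σ·g₂)²).

t is 150, 250 and 255 for T1-, T2- and PD-weighted contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["PhantomSpec", "NoiseSpec", "BRIGHTEST_TISSUE", "generate_phantom", "add_rician_noise"]

BRIGHTEST_TISSUE = {"T1": 150.0, "T2": 250.0, "PD": 255.0}

# tissue plateaus as fractions of the brightest intensity t
_DEFAULT_TISSUE_FRACTIONS = (0.3, 0.65, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of a synthetic multi-tissue phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    modality: str = "T1"
    tissue_intensities: tuple[float, ...] | None = None  # default: fractions of t
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in BRIGHTEST_TISSUE:
            raise ValueError(f"modality must be one of {tuple(BRIGHTEST_TISSUE)}")
        if len(self.shape) != 3:
            raise ValueError("shape must be 3D")

    @property
    def t(self) -> float:
        """Brightest-tissue intensity for the modality."""
        return BRIGHTEST_TISSUE[self.modality]

    def intensities(self) -> tuple[float, ...]:
        if self.tissue_intensities is not None:
            vals = tuple(float(x) for x in self.tissue_intensities)
            if max(vals) != self.t or min(vals) < 0:
                raise ValueError("tissue intensities must lie in [0, t] with max == t")
            return vals
        return tuple(f * self.t for f in _DEFAULT_TISSUE_FRACTIONS)


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level as a percentage of the brightest tissue.

    sigma = (percent/100)·t; the phase θ is fixed at 0.
    """

    percent: float
    t: float = 150.0
    seed: int = 0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.percent < 0:
            raise ValueError("noise percent must be non-negative")
        if self.theta != 0.0:
            raise ValueError("only theta = 0 is modelled")

    @property
    def sigma(self) -> float:
        return self.percent / 100.0 * self.t


def generate_phantom(spec: PhantomSpec | None = None) -> Volume:
    """Deterministic piecewise-constant brain-like phantom.

    A head ellipsoid (semi-axes ≈ 0.42·extent, leaving a background
    fraction ≥ 0.25) carries a mid-intensity outer shell — the
    skull/scalp analogue that makes the head outline clearly brighter
    than the background, as automatic background extraction assumes —
    and an interior partitioned into tissue classes by quantile
    thresholds of a smoothed seeded Gaussian random field modulated by a
    radial gradient, giving nested blob-like regions.  The brightest
    class is forced non-empty, so the volume maximum equals t exactly.
    """
    spec = spec or PhantomSpec()
    shape = spec.shape
    if min(shape) < 16:
        raise ValueError("shape too small for the phantom geometry (need >= 16 per axis)")
    rng = np.random.default_rng(spec.geometry_seed)

    grids = np.meshgrid(*(np.linspace(-1.0, 1.0, n) for n in shape), indexing="ij")
    semi = (0.84, 0.90, 0.80)  # semi-axes in [-1,1] coords -> background fraction ~0.68
    radial = sum((g / s) ** 2 for g, s in zip(grids, semi))
    head = radial <= 1.0
    shell = head & (radial >= 0.80)  # skull/scalp analogue
    interior = radial < 0.80

    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=[n / 10.0 for n in shape], mode="reflect")
    field = field / (field.std() + 1e-12) - 0.8 * radial  # blobs nested toward the centre

    intensities = sorted(spec.intensities())
    inside = field[interior]
    qs = np.quantile(inside, np.linspace(0.0, 1.0, len(intensities) + 1)[1:-1])
    labels = np.digitize(field, qs)  # 0..n_classes-1

    data = np.zeros(shape, dtype=np.float64)
    for cls, val in enumerate(intensities):
        data[interior & (labels == cls)] = val
    data[shell] = intensities[len(intensities) // 2]
    if not np.any(data == intensities[-1]):  # guard: brightest class emptied by quantiles
        data[interior & (field >= np.max(inside))] = intensities[-1]
    return Volume(data)


def add_rician_noise(clean: Volume, spec: NoiseSpec) -> Volume:
    """Corrupt a noiseless magnitude volume with Rician noise.

    Both Gaussian fields are driven from one seed via a SeedSequence
    split, so a single integer reproduces the noisy volume bitwise.
    """
    if np.any(clean.data < 0):
        raise ValueError("clean volume must be non-negative")
    if spec.percent == 0:
        return clean.with_data(clean.data.copy())
    s1, s2 = np.random.SeedSequence(spec.seed).spawn(2)
    g1 = np.random.default_rng(s1).standard_normal(clean.shape)
    g2 = np.random.default_rng(s2).standard_normal(clean.shape)
    sigma = spec.sigma
    return clean.with_data(np.hypot(clean.data + sigma * g1, sigma * g2))
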