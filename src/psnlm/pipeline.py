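"""End-to-end denoising variants and their evaluation.

Five variants are orchestrated around the same NLM core:

=========  ==============================  ===========  ==============
variant    transform                       pre-smooth   bias handling
=========  ==============================  ===========  ==============
NLM        none (raw magnitude)            none         none
UNLM1      squared magnitude               none         subtract 2σ², sqrt
PSNLM1     squared magnitude               yes          subtract 2σ², sqrt
UNLM2      forward VST                     none         exact-unbiased inverse VST
PSNLM2     forward VST                     yes          exact-unbiased inverse VST
=========  ==============================  ===========  ==============

σ comes either from the user or from the background of the unsmoothed
squared magnitude (Otsu-based extraction).  UNLM1/UNLM2 are exactly
PSNLM1/PSNLM2 with the identity pre-smoother, and are implemented as
such, so the reduction is bitwise.

The filtering degree h, when not given, defaults to h_scale times a
representative noise scale of the filtered domain: σ for the raw
magnitude, 1 for the VST domain (stabilized noise std), and
2σ·sqrt(mean |z|² over the head) for the squared domain, whose noise std
2σ·sqrt(r² + σ²) is signal-dependent.  When a ground-truth reference is
available, :func:`select_h` grid-searches h for maximum PSNR instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .background import SegmentationConfig, extract_background
from .nlm import NLMParams, nlm_denoise, psnlm_denoise
from .noise import NoiseEstimate, estimate_sigma, squared_magnitude, unbias_squared
from .presmooth import PresmoothConfig, presmooth
from .volume import Mask, Volume, check_same_shape
from .vst import VSTConfig, VSTTable, build_vst, forward_vst, inverse_vst

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "denoise",
    "run_psnlm1",
    "run_psnlm2",
    "select_h",
    "evaluate",
]

VARIANTS = ("NLM", "UNLM1", "UNLM2", "PSNLM1", "PSNLM2")

_H_FLOOR = 1e-12  # keeps NLM well-defined (identity) when sigma estimates to 0

_vst_cache: dict[VSTConfig, VSTTable] = {}


def _vst_table(cfg: VSTConfig) -> VSTTable:
    if cfg not in _vst_cache:
        _vst_cache[cfg] = build_vst(cfg)
    return _vst_cache[cfg]


@dataclass(frozen=True)
class PipelineConfig:
    """Variant selection plus every stage's parameters.

    sigma_source is ``auto_background`` (Otsu extraction + background
    mean of the squared magnitude) or ``user_value`` (sigma_value).
    h_grid is only consumed by :func:`select_h`.  A PSNLM variant with
    the identity pre-smoother is allowed — it *is* the UNLM baseline.
    """

    variant: str = "PSNLM2"
    presmooth: PresmoothConfig = field(default_factory=PresmoothConfig)
    nlm: NLMParams = field(default_factory=NLMParams)
    sigma_source: str = "auto_background"
    sigma_value: float | None = None
    h_scale: float = 1.0
    h_grid: tuple[float, ...] | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    vst: VSTConfig = field(default_factory=VSTConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.sigma_source not in ("auto_background", "user_value"):
            raise ValueError("sigma_source must be 'auto_background' or 'user_value'")
        if self.sigma_source == "user_value" and self.sigma_value is None:
            raise ValueError("sigma_value required with sigma_source='user_value'")


def _resolve_sigma(noisy: Volume, config: PipelineConfig, mask: Mask | None) -> tuple[float, Mask | None]:
    if config.sigma_source == "user_value":
        return float(config.sigma_value), mask
    if mask is None:
        mask = extract_background(noisy, config.segmentation)
    est = estimate_sigma(squared_magnitude(noisy), mask)
    return est.sigma, mask


def _resolve_h(config: PipelineConfig, domain_scale: float) -> NLMParams:
    if config.nlm.h is not None:
        return config.nlm
    return replace(config.nlm, h=max(config.h_scale * domain_scale, _H_FLOOR))


def run_psnlm1(noisy: Volume, config: PipelineConfig, mask: Mask | None = None) -> Volume:
    """Squared-magnitude pathway (PSNLM1; UNLM1 with identity pre-smoother).

    background → σ → square → pre-smooth → NLM with pre-smoothed weights
    → subtract 2σ², clamp, square root.
    """
    sigma, mask = _resolve_sigma(noisy, config, mask)
    sq = squared_magnitude(noisy)
    guide = presmooth(sq, config.presmooth)
    if mask is not None and np.any(~mask.data):
        m2 = float(sq.data[~mask.data].mean())
    else:
        m2 = float(sq.data.mean())
    params = _resolve_h(config, 2.0 * sigma * math.sqrt(max(m2, sigma ** 2)))
    den = psnlm_denoise(sq, guide, params)
    return unbias_squared(den, sigma)


def run_psnlm2(noisy: Volume, config: PipelineConfig, mask: Mask | None = None) -> Volume:
    """VST pathway (PSNLM2; UNLM2 with identity pre-smoother).

    σ → forward VST → pre-smooth → NLM with pre-smoothed weights →
    exact-unbiased inverse VST.
    """
    sigma, mask = _resolve_sigma(noisy, config, mask)
    if sigma == 0.0:
        # zero noise: the stabilizer is undefined (z/σ); nothing to remove
        return noisy.with_data(noisy.data.copy())
    table = _vst_table(config.vst)
    ft = forward_vst(noisy, sigma, table)
    guide = presmooth(ft, config.presmooth)
    params = _resolve_h(config, 1.0)  # stabilized noise std is 1 by construction
    den = psnlm_denoise(ft, guide, params)
    return inverse_vst(den, sigma, table)


def denoise(noisy: Volume, config: PipelineConfig, mask: Mask | None = None) -> Volume:
    """Run the configured variant end to end."""
    if config.variant == "NLM":
        sigma, _ = _resolve_sigma(noisy, config, mask)
        return nlm_denoise(noisy, _resolve_h(config, sigma))
    if config.variant in ("UNLM1", "PSNLM1"):
        cfg = config if config.variant == "PSNLM1" else replace(
            config, presmooth=replace(config.presmooth, method="identity"))
        return run_psnlm1(noisy, cfg, mask)
    cfg = config if config.variant == "PSNLM2" else replace(
        config, presmooth=replace(config.presmooth, method="identity"))
    return run_psnlm2(noisy, cfg, mask)


def evaluate(result: Volume, reference: Volume, C: float | None = None) -> tuple[float, float]:
    """MSE and PSNR (dB) of a denoised volume against the ground truth.

    PSNR = 10·log10(C²/MSE) with C the maximum representable intensity
    (default: the reference maximum).  Identical volumes report MSE 0 and
    PSNR +inf.
    """
    check_same_shape(result, reference)
    if C is None:
        C = float(reference.data.max())
    if C <= 0:
        raise ValueError("C must be positive")
    mse = float(np.mean((result.data - reference.data) ** 2))
    psnr = math.inf if mse == 0.0 else 10.0 * math.log10(C ** 2 / mse)
    return mse, psnr


def select_h(noisy: Volume, reference: Volume, config: PipelineConfig,
             mask: Mask | None = None, C: float | None = None) -> float:
    """Grid-search h for maximum PSNR against a ground-truth reference.

    Candidates are evaluated in increasing order and ties broken by the
    smallest h.
    """
    if not config.h_grid:
        raise ValueError("h_grid is empty")
    check_same_shape(noisy, reference)
    best_h, best_psnr = None, -math.inf
    for h in sorted(config.h_grid):
        cfg = replace(config, nlm=replace(config.nlm, h=float(h)))
        _, psnr = evaluate(denoise(noisy, cfg, mask), reference, C)
        if psnr > best_psnr:
            best_h, best_psnr = float(h), psnr
    return best_h
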