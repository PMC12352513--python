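"""Reduced Daly-style visible-differences predictor.

Maps a pixel-aligned pair of calibrated luminance images to a per-pixel
probability-of-detection map (P_map) and pooled scalars.  The pipeline is the
classic detection cascade:

1. octave band-limited local contrast per sub-band (DoG band over a local
   low-pass luminance mean),
2. contrast *difference* between test and reference, weighted by a contrast
   sensitivity function evaluated at the band's centre frequency (in
   cycles/degree via the display's pixels-per-degree) and at the adapting
   luminance,
3. a Weibull psychometric transducer per band,
4. probability summation across bands: P = 1 - prod_b (1 - p_b).

This is an original, self-contained predictor exposing the same I/O contract
as heavyweight visible-difference metrics (reference image, test image,
display model, viewing mode), not a re-implementation of any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .render import DisplayModel

__all__ = ["VDPConfig", "ProbabilityMap", "csf", "predict", "pool"]

# CSF constants (single source of truth).  S(f, L) = S0(L) (f/fp) exp(1 - f/fp)
# with S0(L) = S_MAX * (L / (L + L_HALF))^L_EXP: a photopic band-pass shape
# peaking at F_PEAK cpd whose gain saturates with adapting luminance.
CSF_CONSTANTS = {
    "F_PEAK": 4.0,    # cpd, peak spatial frequency
    "S_MAX": 250.0,   # asymptotic peak sensitivity
    "L_HALF": 12.5,   # cd/m^2, half-saturation luminance
    "L_EXP": 0.4,     # luminance-response exponent
}


@dataclass(frozen=True)
class VDPConfig:
    """Predictor settings.

    ``mode='side_by_side'`` models comparison of adjacent images by a global
    sensitivity attenuation (``side_by_side_factor``) relative to the more
    sensitive superimposed-flicker viewing.  ``summation_beta`` is the Weibull
    slope used both in the transducer and (implicitly) probability summation.
    Contrast masking is off by default; when enabled, within-band reference
    contrast divisively raises the effective threshold.
    """

    ppd: float = 120.0
    display: DisplayModel = field(default_factory=DisplayModel)
    mode: str = "side_by_side"
    summation_beta: float = 3.5
    masking_enabled: bool = False
    side_by_side_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.ppd <= 0:
            raise ValueError("ppd must be > 0")
        if self.summation_beta <= 0:
            raise ValueError("summation_beta must be > 0")
        if self.mode not in ("side_by_side", "flicker"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ProbabilityMap:
    """Per-pixel detection probability plus its pooled summaries."""

    pixels: np.ndarray
    pooled_mean_full: float
    pooled_mean_object: float
    pooled_max: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        self.pixels = np.clip(p, 0.0, 1.0)


def csf(spatial_frequency, adapt_luminance) -> np.ndarray:
    """Contrast sensitivity at a spatial frequency (cpd) and adapting
    luminance (cd/m²).  Band-pass in frequency, saturating in luminance."""
    f = np.asarray(spatial_frequency, dtype=np.float64)
    L = np.asarray(adapt_luminance, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("spatial frequency must be >= 0")
    if np.any(L <= 0):
        raise ValueError("adapting luminance must be > 0")
    c = CSF_CONSTANTS
    s0 = c["S_MAX"] * (L / (L + c["L_HALF"])) ** c["L_EXP"]
    shape = (f / c["F_PEAK"]) * np.exp(1.0 - f / c["F_PEAK"])
    return s0 * shape


def _band_centers_cpi(h: int, w: int) -> list[float]:
    """Octave centre frequencies (cycles/image), pyramid depth
    floor(log2(min(H, W))) - 2."""
    depth = max(int(np.floor(np.log2(min(h, w)))) - 2, 1)
    nyq = min(h, w) / 2.0
    centers = [nyq / 2.0**lev for lev in range(depth)]
    return [c for c in centers if c >= 1.0] or [nyq / 2.0]


def _band_contrast(lum: np.ndarray, center_cpi: float):
    """Band-limited local contrast: DoG band over a local luminance mean."""
    # spatial sigma of a Gaussian whose half-amplitude wavelength matches the band
    sigma = lum.shape[0] / (2.0 * np.pi * center_cpi)
    lo = gaussian_filter(lum, sigma * 2.0, mode="nearest")
    band = gaussian_filter(lum, sigma, mode="nearest") - lo
    return band / np.clip(lo, 1e-6, None)


def predict(ref: np.ndarray, test: np.ndarray,
            cfg: VDPConfig = VDPConfig(),
            mask: np.ndarray | None = None) -> ProbabilityMap:
    """Detection-probability map for a calibrated luminance image pair.

    ``ref`` and ``test`` are (H, W) luminance arrays in cd/m² on the same
    display calibration.  The result is symmetric in its two image arguments
    (the transducer sees only |contrast difference|).
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape or ref.ndim != 2:
        raise ValueError("ref/test must be equal-shape 2-D luminance images")
    if np.any(ref < 0) or np.any(test < 0):
        raise ValueError("luminance must be non-negative")

    h, w = ref.shape
    adapt = float(max(np.mean(0.5 * (ref + test)), cfg.display.black_level, 1e-3))
    sens_scale = cfg.side_by_side_factor if cfg.mode == "side_by_side" else 1.0

    p_none = np.ones_like(ref)  # running prod of (1 - p_b)
    for center in _band_centers_cpi(h, w):
        c_ref = _band_contrast(ref, center)
        c_test = _band_contrast(test, center)
        dc = np.abs(c_test - c_ref)
        f_cpd = center * cfg.ppd / w  # cycles/image -> cycles/degree
        sens = csf(f_cpd, adapt) * sens_scale
        if cfg.masking_enabled:
            sens = sens / (1.0 + np.abs(c_ref) * sens)
        # Weibull transducer: P(detect) at threshold contrast 1/sens
        p_band = 1.0 - np.exp(-((sens * dc) ** cfg.summation_beta))
        p_none *= 1.0 - p_band
    pmap = 1.0 - p_none

    mean_obj = float(pmap[np.asarray(mask, bool)].mean()) if mask is not None else float("nan")
    return ProbabilityMap(
        pixels=pmap,
        pooled_mean_full=float(pmap.mean()),
        pooled_mean_object=mean_obj,
        pooled_max=float(pmap.max()),
    )


def pool(pmap: ProbabilityMap, mode: str = "mean_full",
         mask: np.ndarray | None = None) -> float:
    """Pool a probability map to a scalar: mean_full | mean_object | max."""
    if mode == "mean_full":
        return float(np.mean(pmap.pixels))
    if mode == "max":
        return float(np.max(pmap.pixels))
    if mode == "mean_object":
        if mask is None:
            raise ValueError("mean_object pooling needs an object mask")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("object mask is empty")
        return float(np.mean(pmap.pixels[mask]))
    raise ValueError(f"unknown pooling mode {mode!r}")
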