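"""Highlight-based image statistics for gloss prediction.

Given calibrated luminance images of the same scene rendered with and without
the diffuse term, these routines isolate specular reflections, threshold them
at k% of the peak intensity within the object mask, and summarise the result
with the classic gloss cues: sub-band RMS contrast, highlight coverage,
sharpness (spectral slope and local total variation) and intensity-histogram
skewness.  For an image *pair* the predictor of perceived gloss difference is
the absolute difference of each per-image statistic.

Degenerate inputs (empty highlight sets, constant windows) yield NaN
sentinels with a warning, never silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricConfig",
    "MetricVector",
    "specular_component",
    "threshold_highlights",
    "bandpass_decompose",
    "rms_contrast",
    "coverage",
    "sharpness_spectrum_slope",
    "sharpness_local_tv",
    "histogram_skewness",
    "metrics_for_image",
    "metric_vector_for_pair",
    "DEFAULT_K_VALUES",
]

DEFAULT_K_VALUES: tuple[float, ...] = (0, 1, 3, 5, 10, 20, 30, 40)


@dataclass(frozen=True)
class MetricConfig:
    """Knobs of the metric pipeline.

    ``band_centers`` are radial centre frequencies in cycles/image of the
    Gaussian band-pass (difference-of-Gaussians) ladder; the default is an
    octave ladder 1..128 suited to images of >= 256 px.  ``tv_window`` and
    ``spectrum_window`` set the local window size (pixels) for the two
    sharpness measures, with 50% overlap.
    """

    k_values: tuple[float, ...] = DEFAULT_K_VALUES
    band_centers: tuple[float, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
    tv_window: int = 32
    spectrum_window: int = 32

    def __post_init__(self) -> None:
        if any(not 0 <= k < 100 for k in self.k_values):
            raise ValueError("k values must lie in [0, 100)")
        if len(self.band_centers) < 1:
            raise ValueError("need at least one band")
        if any(b <= a for a, b in zip(self.band_centers, self.band_centers[1:])):
            raise ValueError("band_centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)


@dataclass
class MetricVector:
    """Per-pair scalar predictors at one threshold level k."""

    k: float
    band_contrast: np.ndarray  # |delta| per band
    combined_contrast: float
    coverage: float
    sharpness_slope: float
    sharpness_tv: float
    skewness: float
    vdp_mean_full: float = np.nan  # filled by the vdp module
    vdp_mean_object: float = np.nan
    vdp_max: float = np.nan
    per_image: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "k": self.k,
            "combined_contrast": self.combined_contrast,
            "coverage": self.coverage,
            "sharpness_slope": self.sharpness_slope,
            "sharpness_tv": self.sharpness_tv,
            "skewness": self.skewness,
            "vdp_mean_full": self.vdp_mean_full,
            "vdp_mean_object": self.vdp_mean_object,
            "vdp_max": self.vdp_max,
        }
        for i, c in enumerate(self.band_contrast):
            d[f"band_contrast_{i + 1}"] = c
        return d


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("object mask must contain at least one pixel")
    return mask


def specular_component(full: np.ndarray, diffuse: np.ndarray) -> np.ndarray:
    """Specular luminance: max(full - diffuse, 0), element-wise."""
    full = np.asarray(full, dtype=np.float64)
    diffuse = np.asarray(diffuse, dtype=np.float64)
    if full.shape != diffuse.shape:
        raise ValueError(f"shape mismatch: {full.shape} vs {diffuse.shape}")
    return np.maximum(full - diffuse, 0.0)


def threshold_highlights(spec: np.ndarray, k: float, mask: np.ndarray):
    """Keep pixels brighter than k% of the in-mask peak; zero the rest.

    Returns ``(thresholded image, highlight mask)``.  k = 0 keeps every
    strictly positive pixel.  An all-zero specular image yields an empty
    highlight mask (no error).
    """
    spec = np.asarray(spec, dtype=np.float64)
    mask = _check_mask(mask)
    peak = spec[mask].max() if mask.any() else 0.0
    thresh = (k / 100.0) * peak
    highlight = mask & (spec > thresh) & (spec > 0)
    out = np.where(highlight, spec, 0.0)
    return out, highlight


def _dog_transfer(freq: np.ndarray, center: float) -> np.ndarray:
    # DoG in the frequency domain peaks at sigma_lo * sqrt(8/3 * ln 4)
    sigma_lo = center / np.sqrt(8.0 / 3.0 * np.log(4.0))
    sigma_hi = 2.0 * sigma_lo
    return np.exp(-(freq**2) / (2 * sigma_hi**2)) - np.exp(-(freq**2) / (2 * sigma_lo**2))


def bandpass_decompose(img: np.ndarray, cfg: MetricConfig) -> list[np.ndarray]:
    """Gaussian band-pass (DoG) decomposition at the configured centres.

    Filtering is radial in the 2-D Fourier domain; each band transfer
    function vanishes at DC, so constant images map to (numerically) zero in
    every band and the decomposition is linear in the input.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    nyquist = min(h, w) / 2.0
    if max(cfg.band_centers) > nyquist:
        raise ValueError(
            f"band centre {max(cfg.band_centers)} c/img exceeds Nyquist {nyquist}"
        )
    fy = np.fft.fftfreq(h) * h  # cycles per image
    fx = np.fft.fftfreq(w) * w
    freq = np.hypot(fy[:, None], fx[None, :])
    spectrum = np.fft.fft2(img)
    return [
        np.real(np.fft.ifft2(spectrum * _dog_transfer(freq, c)))
        for c in cfg.band_centers
    ]


def rms_contrast(img: np.ndarray, mask: np.ndarray) -> float:
    """RMS deviation from the masked mean (population RMS contrast)."""
    mask = _check_mask(mask)
    vals = np.asarray(img, dtype=np.float64)[mask]
    return float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))


def coverage(highlight_mask: np.ndarray, object_mask: np.ndarray) -> float:
    """Fraction of object pixels that are highlighted."""
    object_mask = _check_mask(object_mask)
    highlight_mask = np.asarray(highlight_mask, dtype=bool)
    return float((highlight_mask & object_mask).sum() / object_mask.sum())


def _windows(mask: np.ndarray, size: int):
    """Top-left corners of size×size windows tiling the mask bounding box
    with 50% overlap; windows must intersect the mask."""
    rows, cols = np.where(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if r1 - r0 < size or c1 - c0 < size:
        raise ValueError(f"mask bounding box smaller than window size {size}")
    step = max(size // 2, 1)
    for r in range(r0, r1 - size + 1, step):
        for c in range(c0, c1 - size + 1, step):
            if mask[r:r + size, c:c + size].any():
                yield r, c


def sharpness_spectrum_slope(img: np.ndarray, mask: np.ndarray,
                             window: int = 32) -> float:
    """Mean over local windows of the log-magnitude vs log-frequency slope.

    Windows with (near-)constant content are excluded; if every window is
    degenerate the slope is undefined and NaN is returned with a warning.
    Sharper structure carries more high-frequency energy, hence a shallower
    (less negative) slope.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = _check_mask(mask)
    fy = np.fft.fftfreq(window) * window
    freq = np.hypot(fy[:, None], fy[None, :])
    sel = (freq >= 1) & (freq <= window / 2)
    logf = np.log(freq[sel])
    slopes = []
    for r, c in _windows(mask, window):
        patch = img[r:r + window, c:c + window]
        if patch.std() < 1e-12:
            continue
        mag = np.abs(np.fft.fft2(patch - patch.mean()))[sel]
        logm = np.log(mag + 1e-12)
        slopes.append(np.polyfit(logf, logm, 1)[0])
    if not slopes:
        warnings.warn("spectrum slope undefined: all windows constant")
        return float("nan")
    return float(np.mean(slopes))


def sharpness_local_tv(img: np.ndarray, mask: np.ndarray,
                       window: int = 32) -> float:
    """Local maximum total variation: max over windows of the mean gradient
    magnitude.  Emphasises the steepest intensity transition on the object."""
    img = np.asarray(img, dtype=np.float64)
    mask = _check_mask(mask)
    gy, gx = np.gradient(img)
    gmag = np.hypot(gy, gx)
    best = 0.0
    for r, c in _windows(mask, window):
        best = max(best, float(gmag[r:r + window, c:c + window].mean()))
    return best


def histogram_skewness(img: np.ndarray, mask: np.ndarray) -> float:
    """Third standardised moment of the masked intensity histogram."""
    mask = _check_mask(mask)
    vals = np.asarray(img, dtype=np.float64)[mask]
    if vals.size < 3 or vals.std() < 1e-15:
        warnings.warn("skewness undefined: <3 pixels or zero variance")
        return float("nan")
    return float(stats.skew(vals))


def metrics_for_image(full_lum: np.ndarray, diffuse_lum: np.ndarray,
                      mask: np.ndarray, k: float,
                      cfg: MetricConfig = MetricConfig()) -> dict:
    """All per-image statistics at one threshold level k.

    Order of operations: diffuse removal, thresholding at k% of the in-mask
    peak, then band decomposition of the thresholded highlight image.
    Skewness is computed on the un-thresholded masked specular luminance.
    """
    mask = _check_mask(mask)
    spec = specular_component(full_lum, diffuse_lum)
    thresholded, highlight = threshold_highlights(spec, k, mask)
    window = min(cfg.tv_window, *thresholded.shape)
    out = {
        "coverage": coverage(highlight, mask),
        "combined_contrast": rms_contrast(thresholded, mask),
        "skewness": histogram_skewness(spec, mask),
    }
    if not highlight.any():
        warnings.warn(f"no highlight pixels at k={k}; sharpness set to NaN/0")
        out["sharpness_slope"] = float("nan")
        out["sharpness_tv"] = 0.0
    else:
        out["sharpness_slope"] = sharpness_spectrum_slope(
            thresholded, mask, min(cfg.spectrum_window, *thresholded.shape))
        out["sharpness_tv"] = sharpness_local_tv(thresholded, mask, window)
    bands = bandpass_decompose(thresholded, cfg)
    for i, band in enumerate(bands):
        out[f"band_contrast_{i + 1}"] = rms_contrast(band, mask)
    return out


def metric_vector_for_pair(
    ref_full: np.ndarray, ref_diffuse: np.ndarray,
    test_full: np.ndarray, test_diffuse: np.ndarray,
    mask: np.ndarray, k: float,
    cfg: MetricConfig = MetricConfig(),
    signed: bool = False,
) -> MetricVector:
    """Pair predictors at one k: |m(test) - m(ref)| for every statistic.

    The absolute difference (default) reflects that the task concerns the
    *size* of the gloss difference; ``signed=True`` keeps the raw difference.
    Per-image values are retained in ``per_image``.
    """
    m_ref = metrics_for_image(ref_full, ref_diffuse, mask, k, cfg)
    m_test = metrics_for_image(test_full, test_diffuse, mask, k, cfg)
    diff = lambda key: (m_test[key] - m_ref[key]) if signed else abs(m_test[key] - m_ref[key])
    bands = np.array([diff(f"band_contrast_{i + 1}") for i in range(cfg.n_bands)])
    return MetricVector(
        k=k,
        band_contrast=bands,
        combined_contrast=diff("combined_contrast"),
        coverage=diff("coverage"),
        sharpness_slope=diff("sharpness_slope"),
        sharpness_tv=diff("sharpness_tv"),
        skewness=diff("skewness"),
        per_image={"ref": m_ref, "test": m_test},
    )
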