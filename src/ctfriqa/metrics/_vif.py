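"""Information-theoretic metrics: information fidelity criterion (IFC) and
visual information fidelity (VIF).

Both model natural-image wavelet coefficients as a Gaussian scale mixture
(GSM) and the distortion as a signal attenuation plus additive Gaussian
noise, estimated locally per coefficient.  IFC sums, over subbands, the
mutual information between reference and distorted coefficients.  VIF
additionally passes both signals through an additive-noise "visual channel"
(variance ``sigma_nsq``) and reports the ratio of the information the
distorted image retains to the information the reference carries, so
identical images score exactly 1.

The default decomposition is a separable wavelet pyramid (sym4, 4 levels);
a Gaussian-pyramid pixel-domain variant is available via ``domain="pixel"``.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ._common import as_float_pair

WAVELET = "sym4"
LEVELS = 4
WINDOW = 3
VIF_SIGMA_NSQ = 2.0
_EPS = 1e-10
#: Variance floor standing in for intrinsic neural noise; keeps the
#: mutual-information sum finite on identical images.
IFC_VAR_FLOOR = 1e-6


def _local_stats(x: np.ndarray, y: np.ndarray, size: int = WINDOW):
    mx = ndimage.uniform_filter(x, size=size, mode="reflect")
    my = ndimage.uniform_filter(y, size=size, mode="reflect")
    sxx = np.maximum(ndimage.uniform_filter(x * x, size=size, mode="reflect") - mx * mx, 0.0)
    syy = np.maximum(ndimage.uniform_filter(y * y, size=size, mode="reflect") - my * my, 0.0)
    sxy = ndimage.uniform_filter(x * y, size=size, mode="reflect") - mx * my
    return sxx, syy, sxy


def _gsm_channel(band_ref: np.ndarray, band_dist: np.ndarray):
    """Per-coefficient channel estimate: gain g and residual noise variance."""
    sxx, syy, sxy = _local_stats(band_ref, band_dist)
    g = sxy / (sxx + _EPS)
    sv = syy - g * sxy
    neg = g < 0
    sv = np.where(neg, syy, sv)
    g = np.where(neg, 0.0, g)
    sv = np.maximum(sv, 0.0)
    return g, sv, sxx


def _subbands(ref: np.ndarray, dist: np.ndarray, levels: int):
    lev = min(levels, pywt.dwtn_max_level(ref.shape, WAVELET))
    cr = pywt.wavedec2(ref, WAVELET, level=lev)
    cd = pywt.wavedec2(dist, WAVELET, level=lev)
    for dr, dd in zip(cr[1:], cd[1:]):
        yield from zip(dr, dd)


def _pixel_bands(ref: np.ndarray, dist: np.ndarray, scales: int = 4):
    """Gaussian-pyramid band set used by the pixel-domain variant."""
    for s in range(scales):
        n = 2 ** (4 - s) + 1
        sd = n / 5.0
        yield (
            ref - ndimage.gaussian_filter(ref, sd, mode="reflect"),
            dist - ndimage.gaussian_filter(dist, sd, mode="reflect"),
        )
        if s < scales - 1:
            ref = ndimage.gaussian_filter(ref, sd, mode="reflect")[::2, ::2]
            dist = ndimage.gaussian_filter(dist, sd, mode="reflect")[::2, ::2]


def ifc_band_terms(pair, levels: int = LEVELS) -> list[float]:
    """Per-subband mutual-information terms; :func:`ifc` is their sum."""
    ref, dist = as_float_pair(pair)
    terms = []
    for band_ref, band_dist in _subbands(ref, dist, levels):
        g, sv, sxx = _gsm_channel(band_ref, band_dist)
        info = np.log2(1.0 + g * g * sxx / (sv + IFC_VAR_FLOOR))
        terms.append(float(info.sum()))
    return terms


def ifc(pair, levels: int = LEVELS) -> float:
    """Information fidelity criterion (>= 0, unbounded above; additive over
    subbands; near 0 when the distorted image is independent of the
    reference)."""
    return float(sum(ifc_band_terms(pair, levels)))


def vif(pair, sigma_nsq: float = VIF_SIGMA_NSQ, levels: int = LEVELS, domain: str = "wavelet") -> float:
    """Visual information fidelity; 1.0 for identical images, -> 0 for
    information-destroying distortions, may exceed 1 for contrast gains."""
    ref, dist = as_float_pair(pair)
    if domain == "wavelet":
        bands = _subbands(ref, dist, levels)
    elif domain == "pixel":
        bands = _pixel_bands(ref, dist)
    else:
        raise ValueError(f"unknown VIF domain {domain!r}")
    num = 0.0
    den = 0.0
    for band_ref, band_dist in bands:
        g, sv, sxx = _gsm_channel(band_ref, band_dist)
        num += float(np.log2(1.0 + g * g * sxx / (sv + sigma_nsq)).sum())
        den += float(np.log2(1.0 + sxx / sigma_nsq).sum())
    if den == 0.0:
        return 1.0  # constant images carry no reference information
    return float(num / den)
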