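"""The SSIM family: single-scale SSIM, multi-scale SSIM, and
information-content-weighted SSIM.

All three follow the canonical constructions: an 11x11 Gaussian window
(sigma 1.5) computes local luminance/contrast/structure statistics; the
multi-scale variant re-evaluates contrast and structure on a dyadic pyramid
with the published exponents; the information-weighted variant replaces mean
pooling with weights derived from a local Gaussian scale-mixture model of
band-pass (Laplacian-pyramid) coefficients, so textured, information-rich
regions dominate the pooled score.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import as_float_pair

WIN_SIZE = 11
WIN_SIGMA = 1.5
K1, K2 = 0.01, 0.03
L = 255.0

#: Canonical per-scale exponents for the 5-scale multi-scale SSIM.
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _gaussian_window() -> np.ndarray:
    r = WIN_SIZE // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    w = np.exp(-0.5 * (x / WIN_SIGMA) ** 2)
    return w / w.sum()


_WIN1D = _gaussian_window()


def _filt_valid(x: np.ndarray) -> np.ndarray:
    """Separable Gaussian-window filtering, 'valid' region only."""
    r = WIN_SIZE // 2
    y = ndimage.correlate1d(x, _WIN1D, axis=0, mode="constant")
    y = ndimage.correlate1d(y, _WIN1D, axis=1, mode="constant")
    return y[r:-r, r:-r]


def ssim_maps(ref: np.ndarray, dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return the local (luminance, contrast-structure) similarity maps.

    The full SSIM map is their product; multi-scale pooling uses them
    separately.  Maps are on the 'valid' grid (input shrunk by the window
    radius on each side).
    """
    c1 = (K1 * L) ** 2
    c2 = (K2 * L) ** 2
    mu1 = _filt_valid(ref)
    mu2 = _filt_valid(dist)
    mu1_sq, mu2_sq, mu12 = mu1 * mu1, mu2 * mu2, mu1 * mu2
    sigma1_sq = _filt_valid(ref * ref) - mu1_sq
    sigma2_sq = _filt_valid(dist * dist) - mu2_sq
    sigma12 = _filt_valid(ref * dist) - mu12
    lum = (2 * mu12 + c1) / (mu1_sq + mu2_sq + c1)
    cs = (2 * sigma12 + c2) / (sigma1_sq + sigma2_sq + c2)
    return lum, cs


def ssim(pair) -> float:
    """Mean single-scale SSIM (Gaussian 11x11 window, K1=0.01, K2=0.03, L=255)."""
    ref, dist = as_float_pair(pair)
    if min(ref.shape) < WIN_SIZE:
        raise ValueError(f"image smaller than the {WIN_SIZE}x{WIN_SIZE} SSIM window")
    lum, cs = ssim_maps(ref, dist)
    return float(np.mean(lum * cs))


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x2 block mean followed by dyadic decimation (odd trailing row/col dropped)."""
    h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    blocks = x[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2)
    return blocks.mean(axis=(1, 3))


def allowed_levels(shape: tuple[int, int], requested: int = 5) -> int:
    """Largest scale count such that the coarsest level still fits the SSIM
    window: ``min(shape) >= WIN_SIZE * 2**(levels-1)``."""
    levels = int(np.floor(np.log2(min(shape) / WIN_SIZE))) + 1
    return max(1, min(requested, levels))


def ms_ssim(pair, levels: int = 5, return_details: bool = False):
    """Multi-scale SSIM with the canonical 5-scale exponents.

    Contrast-structure terms are pooled at every scale; luminance only at the
    coarsest.  On images too small for the requested scale count the count is
    reduced (and reported in the details) and the exponents renormalized.
    """
    ref, dist = as_float_pair(pair)
    levels_used = allowed_levels(ref.shape, levels)
    weights = np.asarray(MSSSIM_WEIGHTS[:levels_used], dtype=np.float64)
    weights = weights / weights.sum()
    score = 1.0
    for lev in range(levels_used):
        lum, cs = ssim_maps(ref, dist)
        if lev < levels_used - 1:
            term = float(np.mean(cs))
            ref, dist = _downsample2(ref), _downsample2(dist)
        else:
            term = float(np.mean(lum * cs))
        score *= max(term, 0.0) ** weights[lev]
    if return_details:
        return float(score), {"levels_used": levels_used}
    return float(score)


# ---------------------------------------------------------------------------
# Information-content-weighted SSIM
# ---------------------------------------------------------------------------

IW_NEIGHBORHOOD = 3
IW_SIGMA_NSQ = 0.4


def _expand2(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Upsample a pyramid level back to ``shape`` (bilinear)."""
    zoom = (shape[0] / x.shape[0], shape[1] / x.shape[1])
    return ndimage.zoom(x, zoom, order=1, mode="nearest", grid_mode=True)


def _local_stats(x: np.ndarray, y: np.ndarray, size: int):
    mx = ndimage.uniform_filter(x, size=size, mode="reflect")
    my = ndimage.uniform_filter(y, size=size, mode="reflect")
    sxx = ndimage.uniform_filter(x * x, size=size, mode="reflect") - mx * mx
    syy = ndimage.uniform_filter(y * y, size=size, mode="reflect") - my * my
    sxy = ndimage.uniform_filter(x * y, size=size, mode="reflect") - mx * my
    return np.maximum(sxx, 0.0), np.maximum(syy, 0.0), sxy


def information_weights(
    lap_ref: np.ndarray, lap_dist: np.ndarray, sigma_nsq: float = IW_SIGMA_NSQ
) -> np.ndarray:
    """Per-pixel information content of a band-pass level.

    Local Gaussian scale-mixture statistics over a 3x3 neighborhood give a
    gain ``g`` and residual variance for the distortion channel; the weight is
    the information the reference carries plus what survives the channel:
    ``log2(1 + g^2 sx^2/(sv^2 + sn^2) + sx^2/sn^2)``.
    """
    eps = 1e-12
    sxx, syy, sxy = _local_stats(lap_ref, lap_dist, IW_NEIGHBORHOOD)
    g = sxy / (sxx + eps)
    sv = np.maximum(syy - g * sxy, 0.0)
    g = np.maximum(g, 0.0)
    return np.log2(1.0 + g * g * sxx / (sv + sigma_nsq) + sxx / sigma_nsq)


def iw_ssim(
    pair,
    levels: int = 5,
    sigma_nsq: float = IW_SIGMA_NSQ,
    uniform_weights: bool = False,
    return_details: bool = False,
):
    """Information-content-weighted SSIM.

    Identical to :func:`ms_ssim` except that per-scale maps are pooled with
    information-content weights computed from the Laplacian-pyramid
    coefficients of reference and distorted images.  ``uniform_weights=True``
    degrades the pooling to plain means, reproducing MS-SSIM.
    """
    ref, dist = as_float_pair(pair)
    levels_used = allowed_levels(ref.shape, levels)
    weights = np.asarray(MSSSIM_WEIGHTS[:levels_used], dtype=np.float64)
    weights = weights / weights.sum()
    r = WIN_SIZE // 2
    score = 1.0
    for lev in range(levels_used):
        lum, cs = ssim_maps(ref, dist)
        last = lev == levels_used - 1
        qmap = (lum * cs) if last else cs
        if uniform_weights:
            term = float(np.mean(qmap))
        else:
            ref_lo = _downsample2(ref)
            dist_lo = _downsample2(dist)
            lap_ref = ref - _expand2(ref_lo, ref.shape)
            lap_dist = dist - _expand2(dist_lo, dist.shape)
            w = information_weights(lap_ref, lap_dist, sigma_nsq)[r:-r, r:-r]
            wsum = float(w.sum())
            term = float((w * qmap).sum() / wsum) if wsum > 0 else float(np.mean(qmap))
        score *= max(term, 0.0) ** weights[lev]
        if not last:
            ref, dist = _downsample2(ref), _downsample2(dist)
    if return_details:
        return float(score), {"levels_used": levels_used}
    return float(score)
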