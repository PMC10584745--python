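"""Visual signal-to-noise ratio.

Operates on the error signal (distorted minus reference).  A separable DWT
splits the error into octave bands; each band's RMS contrast (relative to
the mean display luminance) is compared against a contrast detection
threshold derived from the contrast sensitivity function at that band's
spatial frequency.  If no band is visible the distortion is declared
imperceptible and the score caps.  Otherwise the score is an SNR between
the reference's RMS contrast and a visible-distortion measure combining the
perceived contrast of the error (low-level) with a global-precedence term —
the departure of the band-contrast profile from a coarse-dominant
(non-increasing with spatial frequency) profile (mid-level).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.optimize import isotonic_regression

from ._common import DEFAULT_CAP_DB, as_float_pair

WAVELET = "bior4.4"
MAX_LEVELS = 5
PIX_PER_DEG = 32.0
BASE_THRESHOLD = 0.01
ALPHA = 0.04  # weight of the perceived-contrast term in visible distortion


def _csf(f: float) -> float:
    f = max(f, 1e-3)
    a = 2.6 * (0.0192 + 0.114 * f) * np.exp(-((0.114 * f) ** 1.1))
    return float(a / 0.9809)


def band_contrasts(err: np.ndarray, mean_lum: float) -> tuple[np.ndarray, np.ndarray]:
    """RMS contrast per DWT level of the error signal and the corresponding
    band center frequencies (cycles/degree), finest level first."""
    levels = min(MAX_LEVELS, pywt.dwtn_max_level(err.shape, WAVELET))
    levels = max(levels, 1)
    coeffs = pywt.wavedec2(err, WAVELET, level=levels)
    contrasts = []
    freqs = []
    for m, detail in enumerate(reversed(coeffs[1:]), start=1):  # finest -> coarsest
        energy = sum(float(np.mean(d**2)) for d in detail) / 3.0
        contrasts.append(np.sqrt(energy) / mean_lum)
        freqs.append(PIX_PER_DEG / 2.0**m)
    return np.asarray(contrasts), np.asarray(freqs)


def _global_precedence_distance(contrasts: np.ndarray) -> float:
    """Distance of the (finest-first) contrast profile from the nearest
    global-precedence-consistent profile.

    Coarse image structure is perceived first, so distortion energy parked
    in coarse (low-frequency) bands disrupts perception most; a
    GP-consistent error profile has contrast non-increasing from fine to
    coarse.  The term is the Euclidean distance to the isotonic projection
    onto that cone."""
    fit = isotonic_regression(contrasts, increasing=False).x
    return float(np.sqrt(np.sum((contrasts - fit) ** 2)))


def vsnr(pair, alpha: float = ALPHA, cap_db: float = DEFAULT_CAP_DB) -> tuple[float, bool]:
    """VSNR in dB; below-threshold (imperceptible) distortion reports the cap
    with the cap flag set.  Returns ``(score_db, capped)``."""
    ref, dist = as_float_pair(pair)
    err = dist - ref
    mean_lum = float(np.mean(ref)) + 1.0
    contrasts, freqs = band_contrasts(err, mean_lum)
    thresholds = np.array([BASE_THRESHOLD / _csf(f) for f in freqs])
    visible = contrasts >= thresholds
    if not visible.any():
        return cap_db, True
    c_img = float(np.std(ref)) / mean_lum
    d_pc = float(np.sqrt(np.sum(contrasts[visible] ** 2)))
    d_gp = _global_precedence_distance(contrasts)
    vd = alpha * d_pc + (1.0 - alpha) * d_gp / np.sqrt(2.0)
    if vd <= 0.0:
        return cap_db, True
    value = 10.0 * np.log10(c_img**2 / vd**2)
    if value >= cap_db:
        return cap_db, True
    return float(value), False
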