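"""Noise quality measure.

Models how additive degradation survives human contrast perception: both
images are decomposed into a band-pass contrast pyramid (octave-spaced
Gaussian low-pass differences, local contrast normalized by the local
luminance), band contrasts below the contrast-sensitivity-function (CSF)
detection threshold are discarded as invisible, the visible contrasts are
recomposed into "model-restored" images, and the score is the SNR (dB)
between the two restorations.  Distortion that perception cannot see does
not count against the image.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import DEFAULT_CAP_DB, as_float_pair

N_BANDS = 4
PIX_PER_DEG = 32.0  # display resolution assumed by the viewing model
BASE_THRESHOLD = 0.01  # detection threshold at the CSF peak (Michelson-like)


def _csf(f: np.ndarray | float) -> np.ndarray | float:
    """Mannos-Sakrison contrast sensitivity, normalized to peak 1."""
    f = np.maximum(np.asarray(f, dtype=np.float64), 1e-3)
    a = 2.6 * (0.0192 + 0.114 * f) * np.exp(-((0.114 * f) ** 1.1))
    return a / 0.9809  # peak value of the unnormalized curve

def band_center_frequencies(n_bands: int = N_BANDS, pix_per_deg: float = PIX_PER_DEG) -> np.ndarray:
    """Octave band centers in cycles/degree, finest first."""
    return pix_per_deg / 2.0 ** (np.arange(n_bands) + 2)


def _model_restore(img: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    low = img
    restored = np.zeros_like(img)
    for k in range(N_BANDS):
        next_low = ndimage.gaussian_filter(low, sigma=2.0**k, mode="reflect")
        band = low - next_low
        lum = next_low + 1.0
        contrast = band / lum
        visible = np.abs(contrast) >= thresholds[k]
        restored += np.where(visible, contrast, 0.0) * lum
        low = next_low
    return restored + low


def nqm(pair, cap_db: float = DEFAULT_CAP_DB) -> tuple[float, bool]:
    """NQM in dB; identical (or perceptually identical) restorations report
    the cap with the cap flag set.  Returns ``(score_db, capped)``."""
    ref, dist = as_float_pair(pair)
    thresholds = BASE_THRESHOLD / np.asarray(_csf(band_center_frequencies()))
    r_ref = _model_restore(ref, thresholds)
    r_dist = _model_restore(dist, thresholds)
    err = float(np.sum((r_ref - r_dist) ** 2))
    sig = float(np.sum(r_ref**2))
    if err == 0.0 or sig == 0.0:
        return cap_db, True
    value = 10.0 * np.log10(sig / err)
    if value >= cap_db:
        return cap_db, True
    return float(value), False
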