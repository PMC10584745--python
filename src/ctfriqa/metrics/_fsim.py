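"""Feature similarity index (grayscale variant).

Quality is judged by how well two low-level feature maps agree: phase
congruency (PC) — the degree to which log-Gabor filter responses across
scales align in phase, a contrast-invariant structure detector — and
gradient magnitude (GM).  Per-pixel similarities of the two maps are
combined multiplicatively and pooled with the pointwise maximum PC as
weight, so the most salient structures dominate the score.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ._common import as_float_pair

N_SCALES = 4
N_ORIENT = 4
MIN_WAVELENGTH = 6.0
MULT = 2.0
SIGMA_ONF = 0.55
T1 = 0.85  # PC similarity constant
T2 = 160.0  # GM similarity constant (Scharr-scaled gradients)
_EPS = 1e-8


def _filter_bank(shape: tuple[int, int]) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor x angular-spread filters, [orient][scale]."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx * fx + fy * fy)
    radius[0, 0] = 1.0  # avoid log(0) at DC; DC is zeroed below
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    # low-pass to suppress corner frequencies of the FFT grid
    lp = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))

    log_gabors = []
    for s in range(N_SCALES):
        f0 = 1.0 / (MIN_WAVELENGTH * MULT**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(SIGMA_ONF) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    bank: list[list[np.ndarray]] = []
    for o in range(N_ORIENT):
        angle = o * np.pi / N_ORIENT
        ds = sintheta * np.cos(angle) - costheta * np.sin(angle)
        dc = costheta * np.cos(angle) + sintheta * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * (np.pi / N_ORIENT / 1.2) ** 2))
        bank.append([lg * spread for lg in log_gabors])
    return bank


def phase_congruency(img: np.ndarray, bank: list[list[np.ndarray]] | None = None) -> np.ndarray:
    """Phase congruency map in [0, 1].

    For each orientation the complex log-Gabor responses are summed over
    scales; the local energy (magnitude of the summed phase vectors) divided
    by the total response amplitude measures phase alignment.  Orientations
    are pooled by summing energies and amplitudes.
    """
    if bank is None:
        bank = _filter_bank(img.shape)
    spectrum = np.fft.fft2(img)
    energy_total = np.zeros(img.shape)
    amplitude_total = np.zeros(img.shape)
    for filters in bank:
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        for filt in filters:
            resp = np.fft.ifft2(spectrum * filt)
            e, o = resp.real, resp.imag
            sum_e += e
            sum_o += o
            amplitude_total += np.sqrt(e * e + o * o)
        energy_total += np.sqrt(sum_e**2 + sum_o**2)
    return energy_total / (amplitude_total + _EPS)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.correlate(img, _SCHARR_X, mode="nearest")
    gy = ndimage.correlate(img, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)


def _downsample_for_fsim(x: np.ndarray) -> np.ndarray:
    f = max(1, int(round(min(x.shape) / 256)))
    if f == 1:
        return x
    y = ndimage.uniform_filter(x, size=f, mode="reflect")
    return y[::f, ::f]


def fsim(pair) -> float:
    """FSIM score in [0, 1]; 1 for identical images; symmetric in its arguments."""
    ref, dist = as_float_pair(pair)
    ref = _downsample_for_fsim(ref)
    dist = _downsample_for_fsim(dist)
    bank = _filter_bank(ref.shape)
    pc1 = phase_congruency(ref, bank)
    pc2 = phase_congruency(dist, bank)
    g1 = gradient_magnitude(ref)
    g2 = gradient_magnitude(dist)
    s_pc = (2 * pc1 * pc2 + T1) / (pc1**2 + pc2**2 + T1)
    s_g = (2 * g1 * g2 + T2) / (g1**2 + g2**2 + T2)
    pcm = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pcm).sum() / (pcm.sum() + _EPS))
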