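"""Nine full-reference image quality metrics.

Each metric maps a (reference, distorted) pair of equal-shape 8-bit
grayscale images to a scalar where higher means better quality.  PSNR, NQM
and VSNR are dB-scaled and unbounded at zero/imperceptible distortion; they
are capped (default 100 dB) with an explicit flag so downstream regression
always sees finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._common import DEFAULT_CAP_DB, PairingError, as_float_pair
from ._fsim import fsim
from ._nqm import nqm
from ._psnr import psnr
from ._ssim import iw_ssim, ms_ssim, ssim, ssim_maps
from ._vif import ifc, ifc_band_terms, vif
from ._vsnr import vsnr

#: Canonical reporting order.
METRIC_NAMES = ("PSNR", "SSIM", "FSIM", "IFC", "VIF", "NQM", "VSNR", "MSSSIM", "IWSSIM")


@dataclass
class MetricScoreVector:
    """All nine scores for one image pair, with per-metric cap flags and any
    per-metric failures recorded (a failing metric never aborts the batch)."""

    scores: dict[str, float] = field(default_factory=dict)
    cap_flags: dict[str, bool] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict:
        row: dict = {}
        for name in METRIC_NAMES:
            row[name] = self.scores.get(name, float("nan"))
        for name in METRIC_NAMES:
            row[f"{name}_capped"] = self.cap_flags.get(name, False)
        return row


_DISPATCH = {
    "PSNR": lambda pair: psnr(pair),
    "SSIM": lambda pair: (ssim(pair), False),
    "FSIM": lambda pair: (fsim(pair), False),
    "IFC": lambda pair: (ifc(pair), False),
    "VIF": lambda pair: (vif(pair), False),
    "NQM": lambda pair: nqm(pair),
    "VSNR": lambda pair: vsnr(pair),
    "MSSSIM": lambda pair: (ms_ssim(pair), False),
    "IWSSIM": lambda pair: (iw_ssim(pair), False),
}


def compute_all(pair) -> MetricScoreVector:
    """Evaluate all nine metrics on one pair.

    Deterministic; metric order (and hence serialization order) is fixed by
    :data:`METRIC_NAMES`.
    """
    as_float_pair(pair)  # validate shapes once up front
    out = MetricScoreVector()
    for name in METRIC_NAMES:
        try:
            value, capped = _DISPATCH[name](pair)
        except Exception as exc:  # noqa: BLE001 - recorded per metric
            out.errors[name] = f"{type(exc).__name__}: {exc}"
            continue
        out.scores[name] = float(value)
        out.cap_flags[name] = bool(capped)
    return out


__all__ = [
    "METRIC_NAMES",
    "MetricScoreVector",
    "DEFAULT_CAP_DB",
    "PairingError",
    "compute_all",
    "psnr",
    "ssim",
    "ssim_maps",
    "ms_ssim",
    "iw_ssim",
    "fsim",
    "ifc",
    "ifc_band_terms",
    "vif",
    "nqm",
    "vsnr",
]
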