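"""Shared plumbing for the FR-IQA metric implementations."""

from __future__ import annotations

import numpy as np

#: Finite stand-in for "perfect / imperceptible" on dB-scaled metrics.
DEFAULT_CAP_DB = 100.0


class PairingError(ValueError):
    """Reference / distorted images cannot be compared (shape mismatch)."""


def as_float_pair(pair) -> tuple[np.ndarray, np.ndarray]:
    """Accept an ImagePair or a (reference, distorted) array tuple and return
    float64 arrays of identical shape."""
    if hasattr(pair, "reference"):
        ref, dist = pair.reference.pixels, pair.distorted.pixels
    else:
        ref, dist = pair
    ref = np.asarray(ref, dtype=np.float64)
    dist = np.asarray(dist, dtype=np.float64)
    if ref.ndim != 2 or ref.shape != dist.shape:
        raise PairingError(
            f"reference and distorted must be equal-shape 2-D, got {ref.shape} vs {dist.shape}"
        )
    return ref, dist
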