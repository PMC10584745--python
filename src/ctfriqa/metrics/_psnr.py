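"""Peak signal-to-noise ratio."""

from __future__ import annotations

import numpy as np

from ._common import DEFAULT_CAP_DB, as_float_pair


def psnr(pair, cap_db: float = DEFAULT_CAP_DB) -> tuple[float, bool]:
    """PSNR in dB for 8-bit images: ``10 log10(255^2 / MSE)``.

    Identical images (zero MSE) report the cap with the cap flag set, so the
    score stays finite for downstream regression.

    Returns ``(score_db, capped)``.
    """
    ref, dist = as_float_pair(pair)
    mse = float(np.mean((ref - dist) ** 2))
    if mse == 0.0:
        return cap_db, True
    value = 10.0 * np.log10(255.0**2 / mse)
    if value >= cap_db:
        return cap_db, True
    return float(value), False
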