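"""Shared fixtures: small phantom displays and distorted pairs.

Everything is generated programmatically with fixed seeds; phantom size 128
keeps metric computation fast while leaving room for 4-5 dyadic scales.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctfriqa.ct_prep import apply_crop, auto_crop_threshold, crop_background, window_to_display
from ctfriqa.distortions import DistortionSpec, ImagePair, derive_seed, distort
from ctfriqa.observer_sim import PhantomSpec, synthesize

PHANTOM_SIZE = 128
SITES = ("head", "chest", "abdomen")


@pytest.fixture(scope="session", params=SITES)
def site(request):
    return request.param


@pytest.fixture(scope="session")
def phantoms():
    """One synthesized phantom (image + masks) per site."""
    return {s: synthesize(PhantomSpec(site=s, size=PHANTOM_SIZE, seed=5)) for s in SITES}


@pytest.fixture(scope="session")
def displays(phantoms):
    """Windowed (uncropped) display image per site."""
    return {s: window_to_display(ph.image) for s, ph in phantoms.items()}


@pytest.fixture(scope="session")
def cropped_refs(displays):
    out = {}
    for s, disp in displays.items():
        box = crop_background(disp, threshold=auto_crop_threshold(disp.window)).crop_box
        out[s] = apply_crop(disp, box)
    return out


def make_pair(display, sigma_noise, sigma_blur, base_seed=42):
    """Distort the full display frame, then crop both members identically."""
    box = crop_background(display, threshold=auto_crop_threshold(display.window)).crop_box
    spec = DistortionSpec(
        sigma_noise, sigma_blur, derive_seed(base_seed, display.source_id, sigma_noise, sigma_blur)
    )
    dist = distort(display, spec)
    return ImagePair(
        reference=apply_crop(display, box), distorted=apply_crop(dist, box), spec=spec
    )


@pytest.fixture(scope="session")
def head_pair(displays):
    """A moderately distorted head pair used across metric tests."""
    return make_pair(displays["head"], 14.0, 0.9)


@pytest.fixture(scope="session")
def identical_pair(cropped_refs):
    ref = cropped_refs["head"]
    return ImagePair(reference=ref, distorted=ref, spec=DistortionSpec(0.0, 0.0, 0))


@pytest.fixture(scope="session")
def random_pair_32():
    """Small random pair for brute-force oracles."""
    rng = np.random.default_rng(7)
    ref = rng.integers(0, 256, (32, 32))
    dist = np.clip(ref + rng.normal(0, 12, (32, 32)), 0, 255).astype(int)
    return ref.astype(np.uint8), dist.astype(np.uint8)
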