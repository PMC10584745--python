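"""Gaussian noise / Gaussian blur distortion grids for display images.

The benchmark design applies each of five noise grades (standard deviation in
8-bit gray levels), each of five blur grades (Gaussian kernel standard
deviation in pixels), and all 25 noise x blur combinations to every reference
image: 35 distorted images per reference, 210 for the six-reference study.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_prep import DisplayImage, apply_crop, auto_crop_threshold, crop_background

#: Noise grades: standard deviation in gray levels of the 8-bit display image.
NOISE_GRID = (6.0, 9.0, 14.0, 21.0, 30.0)
#: Blur grades: Gaussian kernel standard deviation in pixels.
BLUR_GRID = (0.6, 0.9, 1.4, 2.1, 3.0)

GAUSS_TRUNCATE = 4.0  # kernel truncated at radius ceil(4*sigma)


@dataclass(frozen=True)
class DistortionSpec:
    """One cell of the distortion grid."""

    sigma_noise: float = 0.0
    sigma_blur: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0 or self.sigma_blur < 0:
            raise ValueError("distortion sigmas must be >= 0")

    @property
    def is_pristine(self) -> bool:
        return self.sigma_noise == 0 and self.sigma_blur == 0

    @property
    def kind(self) -> str:
        """'noise', 'blur', 'combined' or 'none'."""
        if self.is_pristine:
            return "none"
        if self.sigma_blur == 0:
            return "noise"
        if self.sigma_noise == 0:
            return "blur"
        return "combined"


@dataclass(frozen=True)
class ImagePair:
    """A cropped reference and its equally-cropped distorted version."""

    reference: DisplayImage
    distorted: DisplayImage
    spec: DistortionSpec

    def __post_init__(self) -> None:
        if self.reference.pixels.shape != self.distorted.pixels.shape:
            raise ValueError("reference and distorted shapes differ")
        if self.reference.crop_box != self.distorted.crop_box:
            raise ValueError("reference and distorted crop boxes differ")
        if self.reference.source_id != self.distorted.source_id:
            raise ValueError("pair members come from different sources")

    @property
    def pair_id(self) -> str:
        s = self.spec
        return f"{self.reference.source_id}_n{s.sigma_noise:g}_b{s.sigma_blur:g}"

    @property
    def site(self) -> str | None:
        # source ids are "<site><k>" by convention of the phantom generator
        for site in ("head", "chest", "abdomen"):
            if self.reference.source_id.startswith(site):
                return site
        return None


def _as_display(img: DisplayImage, pixels: np.ndarray) -> DisplayImage:
    return DisplayImage(
        pixels=np.clip(np.floor(pixels + 0.5), 0, 255),
        window=img.window,
        source_id=img.source_id,
        crop_box=img.crop_box,
    )


def add_gaussian_noise(img: DisplayImage, sigma: float, seed: int) -> DisplayImage:
    """Add i.i.d. zero-mean Gaussian noise (in float), clip to [0,255], round.

    ``sigma`` is in gray levels of the displayed image.  ``sigma = 0`` returns
    a bit-identical copy; the realization is deterministic given ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return _as_display(img, img.pixels.astype(np.float64))
    rng = np.random.default_rng(seed)
    noisy = img.pixels.astype(np.float64) + rng.normal(0.0, sigma, size=img.pixels.shape)
    return _as_display(img, np.clip(noisy, 0.0, 255.0))


def apply_gaussian_blur(img: DisplayImage, sigma: float) -> DisplayImage:
    """Convolve with a normalized 2-D Gaussian (truncated at 4 sigma, reflect
    borders), then round back to 8 bits.  ``sigma = 0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return _as_display(img, img.pixels.astype(np.float64))
    blurred = ndimage.gaussian_filter(
        img.pixels.astype(np.float64), sigma=sigma, mode="reflect", truncate=GAUSS_TRUNCATE
    )
    return _as_display(img, blurred)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """The normalized 1-D kernel the blur uses (radius ceil(4*sigma))."""
    radius = int(np.ceil(GAUSS_TRUNCATE * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def distort(img: DisplayImage, spec: DistortionSpec, order: str = "blur_first") -> DisplayImage:
    """Apply one grid cell.  With both distortions present, blur is applied
    first by default (system blur precedes detector noise in acquisition)."""
    if order not in ("blur_first", "noise_first"):
        raise ValueError(f"unknown distortion order {order!r}")
    if order == "blur_first":
        out = apply_gaussian_blur(img, spec.sigma_blur)
        out = add_gaussian_noise(out, spec.sigma_noise, spec.seed)
    else:
        out = add_gaussian_noise(img, spec.sigma_noise, spec.seed)
        out = apply_gaussian_blur(out, spec.sigma_blur)
    return out


def derive_seed(base_seed: int, source_id: str, sigma_noise: float, sigma_blur: float) -> int:
    """Deterministic per-cell seed from the study base seed, the reference id
    and the grid coordinates; stable across runs and platforms."""
    tag = f"{source_id}|{sigma_noise:g}|{sigma_blur:g}".encode()
    return (base_seed * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1)


def grid_specs(
    source_id: str,
    noise_levels: tuple[float, ...] = NOISE_GRID,
    blur_levels: tuple[float, ...] = BLUR_GRID,
    base_seed: int = 0,
) -> list[DistortionSpec]:
    """Enumerate the design for one reference: each noise grade alone, each
    blur grade alone, then every combination."""
    cells: list[tuple[float, float]] = []
    cells += [(n, 0.0) for n in noise_levels]
    cells += [(0.0, b) for b in blur_levels]
    cells += [(n, b) for n in noise_levels for b in blur_levels]
    return [
        DistortionSpec(n, b, derive_seed(base_seed, source_id, n, b)) for n, b in cells
    ]


def generate_grid(
    references: list[DisplayImage],
    noise_levels: tuple[float, ...] = NOISE_GRID,
    blur_levels: tuple[float, ...] = BLUR_GRID,
    base_seed: int = 0,
    order: str = "blur_first",
    crop: bool = True,
    crop_threshold: int | None = None,
    crop_margin: int = 2,
) -> list[ImagePair]:
    """Produce the full distortion design over a list of reference images.

    Each reference contributes ``Nn + Nb + Nn*Nb`` pairs.  Distortions are
    applied to the full display frame; the reference's background crop box is
    then applied identically to both members of every pair, mirroring an
    evaluation protocol where metrics see only the diagnostically relevant
    region.  ``crop_threshold=None`` derives the foreground threshold from
    each reference's window (10 gray levels above displayed air), which
    matters for wide lung windows where background air is mid-gray.
    Regenerating with the same ``base_seed`` is bit-identical.
    """
    if not references:
        raise ValueError("need at least one reference image")
    if not noise_levels and not blur_levels:
        raise ValueError("need at least one distortion level")
    pairs: list[ImagePair] = []
    for ref in references:
        if crop:
            thr = crop_threshold if crop_threshold is not None else auto_crop_threshold(ref.window)
            box = crop_background(ref, threshold=thr, margin=crop_margin).crop_box
        else:
            box = None
        ref_c = apply_crop(ref, box) if box else ref
        for spec in grid_specs(ref.source_id, noise_levels, blur_levels, base_seed):
            dist = distort(ref, spec, order=order)
            dist_c = apply_crop(dist, box) if box else dist
            pairs.append(ImagePair(reference=ref_c, distorted=dist_c, spec=spec))
    return pairs
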