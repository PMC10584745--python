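"""CT display preparation: loading, HU windowing, and background cropping.

CT slices are stored as unsigned 16-bit grids with an additive offset so that
negative Hounsfield units (HU) fit in an unsigned type (stored = HU + offset).
For viewing, a window (width W, level L) maps the HU interval
[L - W/2, L + W/2] linearly onto the 8-bit display range; everything below is
black, everything above white.  All distortion and metric computation in this
package operates on these windowed 8-bit display images, and metrics are run
on crops that minimize the diagnostically empty background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

SITES = ("head", "chest", "abdomen")

#: Clinical display windows (width, level) in HU per anatomical site.
SITE_WINDOWS = {
    "head": (80.0, 40.0),
    "chest": (1500.0, -650.0),
    "abdomen": (350.0, 40.0),
}

#: Default storage offset for unsigned-PNG CT exports (stored = HU + offset).
DEFAULT_HU_OFFSET = 32768


class FormatError(ValueError):
    """Raised when an input image violates the expected single-channel format."""


@dataclass(frozen=True)
class WindowSetting:
    """Display window in Hounsfield units."""

    width: float
    level: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @classmethod
    def for_site(cls, site: str) -> "WindowSetting":
        if site not in SITE_WINDOWS:
            raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
        return cls(*SITE_WINDOWS[site])


@dataclass(frozen=True)
class RawCTImage:
    """A stored CT slice: unsigned 16-bit pixels plus its HU convention."""

    pixels: np.ndarray
    site: str
    hu_offset: int = DEFAULT_HU_OFFSET
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 65535:
            raise ValueError("pixel values must lie in [0, 65535]")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        object.__setattr__(self, "pixels", px.astype(np.uint16))

    @property
    def hounsfield(self) -> np.ndarray:
        """Pixel grid converted back to (float) Hounsfield units."""
        return self.pixels.astype(np.float64) - float(self.hu_offset)


@dataclass(frozen=True)
class DisplayImage:
    """An 8-bit windowed display image, optionally cropped.

    ``crop_box`` is ``(row0, col0, row1, col1)`` half-open, in the coordinate
    frame of the *uncropped* source, recorded so the identical box can be
    applied to a reference/distorted pair.  ``no_foreground`` flags the
    degenerate case where cropping found nothing above threshold and fell
    back to the full frame.
    """

    pixels: np.ndarray
    window: WindowSetting
    source_id: str = ""
    crop_box: tuple[int, int, int, int] | None = None
    no_foreground: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("display values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.crop_box is not None:
            r0, c0, r1, c1 = self.crop_box
            if not (r0 < r1 and c0 < c1 and r0 >= 0 and c0 >= 0):
                raise ValueError(f"degenerate crop_box {self.crop_box}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_raw_png(path: str | Path, site: str, hu_offset: int = DEFAULT_HU_OFFSET) -> RawCTImage:
    """Read an 8- or 16-bit single-channel PNG as a stored CT slice.

    8-bit files are widened to the 16-bit container without rescaling; pixel
    values are preserved exactly.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(im, dtype=np.uint32)
            if arr.max() > 65535:
                raise FormatError(f"{path}: pixel values exceed 16-bit range")
            arr = arr.astype(np.uint16)
        elif im.mode == "L":
            arr = np.asarray(im, dtype=np.uint16)
        else:
            raise FormatError(
                f"{path}: expected single-channel grayscale PNG, got mode {im.mode!r}"
            )
    return RawCTImage(pixels=arr, site=site, hu_offset=hu_offset, id=path.stem)


def save_raw_png(img: RawCTImage, path: str | Path) -> None:
    """Write a stored slice as a 16-bit grayscale PNG (lossless round trip)."""
    Image.fromarray(img.pixels.astype(np.uint16)).save(Path(path))


def save_display_png(img: DisplayImage, path: str | Path) -> None:
    Image.fromarray(img.pixels, mode="L").save(Path(path))


def window_to_display(raw: RawCTImage, window: WindowSetting | None = None) -> DisplayImage:
    """Map stored values to 8-bit display gray through a HU window.

    With HU = stored − hu_offset, the displayed value is
    ``255 * (HU - (level - width/2)) / width`` clipped to [0, 255] and rounded
    half-up.  The map is monotone in HU and sends the window edges exactly to
    0 and 255.
    """
    if window is None:
        window = WindowSetting.for_site(raw.site)
    hu = raw.hounsfield
    lo = window.level - window.width / 2.0
    v = 255.0 * (hu - lo) / window.width
    v = np.clip(v, 0.0, 255.0)
    v = np.floor(v + 0.5)  # round half-up
    return DisplayImage(pixels=v, window=window, source_id=raw.id)


def air_display_value(window: WindowSetting) -> int:
    """Displayed gray level of air (-1000 HU) under a window; the natural
    background level for automatic cropping.  0 for head/abdomen windows,
    nonzero for wide lung windows whose range extends below air."""
    lo = window.level - window.width / 2.0
    v = 255.0 * (-1000.0 - lo) / window.width
    return int(np.floor(np.clip(v, 0.0, 255.0) + 0.5))


def auto_crop_threshold(window: WindowSetting, offset: int = 10) -> int:
    """Default foreground threshold: ``offset`` gray levels above air."""
    return min(air_display_value(window) + offset, 255)


def _foreground_bbox(
    pixels: np.ndarray, threshold: int, close_radius: int
) -> tuple[int, int, int, int] | None:
    """Bounding box of the largest connected component of pixels >= threshold."""
    fg = pixels >= threshold
    if close_radius > 0:
        struct = ndimage.generate_binary_structure(2, 2)
        fg = ndimage.binary_closing(fg, structure=struct, iterations=close_radius)
    if not fg.any():
        return None
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labels == largest)
    return int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1


def crop_background(
    img: DisplayImage,
    threshold: int = 10,
    margin: int = 2,
    close_radius: int = 0,
) -> DisplayImage:
    """Crop to the largest foreground component's bounding box plus a margin.

    Foreground is ``pixels >= threshold`` (after optional binary closing).
    When no pixel reaches the threshold the full image is returned with the
    ``no_foreground`` flag set.  Cropping an already-cropped image with the
    same parameters is a fixed point whenever the foreground touches the
    crop edges (the usual case after a tight crop).
    """
    box = _foreground_bbox(img.pixels, threshold, close_radius)
    if box is None:
        return replace(img, no_foreground=True)
    h, w = img.pixels.shape
    r0 = max(box[0] - margin, 0)
    c0 = max(box[1] - margin, 0)
    r1 = min(box[2] + margin, h)
    c1 = min(box[3] + margin, w)
    return apply_crop(img, (r0, c0, r1, c1))


def apply_crop(img: DisplayImage, box: tuple[int, int, int, int]) -> DisplayImage:
    """Apply an explicit crop box; used to crop a distorted image with its
    reference's box so both members of a pair share identical geometry."""
    r0, c0, r1, c1 = box
    h, w = img.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"crop box {box} outside image bounds {(h, w)}")
    return replace(img, pixels=img.pixels[r0:r1, c0:c1], crop_box=(r0, c0, r1, c1))


def write_crop_manifest(images: list[DisplayImage], path: str | Path) -> None:
    """Serialize crop boxes to a sidecar JSON manifest keyed by image id."""
    manifest = {
        im.source_id: {"crop_box": list(im.crop_box) if im.crop_box else None}
        for im in images
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
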