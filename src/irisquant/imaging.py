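"""Image I/O and pixel-level colour conversions.

All downstream colour quantities are computed from three representations of
an 8-bit RGB pixel:

* HSV — the classification feature space; hue is stored as a fraction of the
  full circle in ``[0, 1)`` and is defined as 0 for achromatic pixels.
* CIELAB — sRGB primaries and the D65 white point are assumed throughout,
  the universal default for consumer and clinical camera output.
* Relative luminance — the Rec.601 luma weights ``(0.299, 0.587, 0.114)``
  normalised to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import color as skcolor

MIN_DIM = 64

__all__ = [
    "EyeImage",
    "read_image",
    "rgb_to_hsv",
    "rgb_to_lab",
    "relative_luminance",
]


@dataclass
class EyeImage:
    """An 8-bit RGB eye photograph.

    Attributes
    ----------
    pixels : ndarray of shape (H, W, 3), dtype uint8
    sample_id : identifier, defaults to the file stem on read.
    source : originating path, or ``"synthetic"`` for rendered images.
    """

    pixels: np.ndarray
    sample_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("EyeImage requires an H x W x 3 pixel grid")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ValueError(
                f"image {self.sample_id or '<unnamed>'} is {px.shape[0]}x{px.shape[1]}; "
                f"minimum is {MIN_DIM}x{MIN_DIM}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def read_image(path: str | Path) -> EyeImage:
    """Read a PNG/JPEG/TIFF eye photograph as an :class:`EyeImage`.

    Greyscale images are promoted to RGB; an alpha channel is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    return EyeImage(pixels=pixels, sample_id=path.stem, source=str(path))


def write_image(image: EyeImage | np.ndarray, path: str | Path) -> None:
    """Write an RGB pixel grid as PNG (used for debug overlays)."""
    px = image.pixels if isinstance(image, EyeImage) else np.asarray(image, dtype=np.uint8)
    Image.fromarray(px, mode="RGB").save(Path(path))


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB triplets in the last axis")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return arr


def rgb_to_hsv(rgb) -> np.ndarray:
    """Standard hexcone RGB→HSV transform.

    Accepts a single triplet or any array with triplets in the last axis;
    hue is a fraction in ``[0, 1)`` (0 for achromatic pixels), saturation and
    value in ``[0, 1]``.
    """
    arr = _validate_rgb(rgb)
    scalar = arr.ndim == 1
    hsv = skcolor.rgb2hsv(arr.reshape(-1, 1, 3) / 255.0).reshape(arr.shape)
    return hsv[0] if scalar and hsv.ndim > 1 else hsv


# sRGB -> XYZ (linear, D65); the reference white is the matrix's own image of
# (1,1,1) so achromatic inputs map to a* = b* = 0 exactly.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE_D65 = _SRGB_TO_XYZ @ np.ones(3)
_DELTA = 6.0 / 29.0


def rgb_to_lab(rgb) -> np.ndarray:
    """sRGB→XYZ→CIELAB conversion (D65 white point)."""
    arr = _validate_rgb(rgb)
    c = arr / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_D65
    f = np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def relative_luminance(rgb) -> np.ndarray | float:
    """Rec.601 relative luminance ``(0.299 R + 0.587 G + 0.114 B) / 255``."""
    arr = _validate_rgb(rgb)
    lum = (0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]) / 255.0
    return float(lum) if np.ndim(lum) == 0 else lum
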