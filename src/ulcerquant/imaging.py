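"""Image I/O, color-card correction, channel shielding, and brightness ops.

Gastric-ulcer photographs are analysed on raw 8-bit sRGB values (no gamma
linearisation).  The module provides the computational analogues of the
physical acquisition tricks used in erythema photography:

* a color card photographed alongside the specimen corrects per-channel
  color casts (affine gain + offset fitted over the card patches);
* a cellophane film of one color in front of the lens hides the other two
  channels — emulated here by hard channel zeroing;
* low-red pixels (tissue with no erythema) are unified with the background
  so that only erythematous signal survives;
* a white-balance "brightness level" rescales the exposure (level 50 =
  bright, x2; 100 = as shot; 200 = dark, x0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RGBImage",
    "ColorCardMeasurement",
    "ShieldColor",
    "CalibrationError",
    "load_image",
    "save_image",
    "correct_with_card",
    "shield_channel",
    "suppress_low_red",
    "adjust_brightness",
]

ShieldColor = Literal["red", "green", "blue"]
_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


class CalibrationError(ValueError):
    """Raised when a color-card fit is degenerate."""


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit three-channel raster, channels ordered red, green, blue.

    ``pixels`` is an H x W x 3 uint8 array; every channel value lies in
    [0, 255] by construction.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RGBImage):
            return NotImplemented
        return np.array_equal(self.pixels, other.pixels)


@dataclass(frozen=True)
class ColorCardMeasurement:
    """Per-patch mean RGB triples measured on a reference color card."""

    patch_values: np.ndarray  # P x 3 floats in [0, 255]

    def __post_init__(self) -> None:
        vals = np.asarray(self.patch_values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != 3:
            raise ValueError("patch_values must be P x 3")
        if vals.shape[0] < 2:
            raise ValueError("a card needs at least 2 patches")
        if vals.min() < 0 or vals.max() > 255:
            raise ValueError("patch values must lie in [0, 255]")
        object.__setattr__(self, "patch_values", vals)

    @property
    def patch_count(self) -> int:
        return self.patch_values.shape[0]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; half-up is deterministic across platforms
    return np.floor(x + 0.5)


def _clip_u8(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> RGBImage:
    """Read a PNG/TIFF/JPEG file into canonical 8-bit RGB form.

    Higher bit depths are rescaled to 8-bit (full scale maps to 255),
    grayscale inputs are replicated across the three channels, and any
    alpha channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.shape[-1] != 3:
        raise ValueError(f"unsupported channel count {arr.shape[-1]} in {path}")
    if arr.dtype == np.uint16:
        arr = _round_half_up(arr.astype(float) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = _clip_u8(_round_half_up(arr.astype(float)))
    return RGBImage(arr)


def save_image(image: RGBImage, path: str | Path) -> None:
    """Write an image as 8-bit RGB; the format follows the file suffix."""
    iio.imwrite(Path(path), image.pixels)


def correct_with_card(
    image: RGBImage,
    measured: ColorCardMeasurement,
    reference: ColorCardMeasurement,
) -> RGBImage:
    """Correct a color cast using a card photographed in the same scene.

    For each channel an affine map ``ref = gain * measured + offset`` is
    fitted by least squares over the card's patch means and applied to
    every pixel, then clipped back into [0, 255].  When the measured card
    equals the reference the correction is the identity.
    """
    if measured.patch_count != reference.patch_count:
        raise ValueError("measured and reference cards have different patch counts")
    out = image.pixels.astype(float)
    for c in range(3):
        m = measured.patch_values[:, c]
        r = reference.patch_values[:, c]
        if np.ptp(m) == 0:
            raise CalibrationError(
                f"all measured patches identical in channel {c}; affine fit degenerate"
            )
        A = np.column_stack([m, np.ones_like(m)])
        (gain, offset), *_ = np.linalg.lstsq(A, r, rcond=None)
        out[:, :, c] = gain * out[:, :, c] + offset
    return RGBImage(_clip_u8(_round_half_up(out)))


def fit_card_transform(
    measured: ColorCardMeasurement, reference: ColorCardMeasurement
) -> tuple[np.ndarray, np.ndarray]:
    """Return the per-channel (gain, offset) arrays of the card correction."""
    gains = np.empty(3)
    offsets = np.empty(3)
    for c in range(3):
        m = measured.patch_values[:, c]
        r = reference.patch_values[:, c]
        if np.ptp(m) == 0:
            raise CalibrationError(f"degenerate card fit in channel {c}")
        A = np.column_stack([m, np.ones_like(m)])
        (gains[c], offsets[c]), *_ = np.linalg.lstsq(A, r, rcond=None)
    return gains, offsets


def shield_channel(image: RGBImage, color: ShieldColor) -> RGBImage:
    """Keep only one channel, zeroing the other two.

    The computational analogue of photographing through a cellophane film:
    a red film passes the red channel and hides green and blue markers
    entirely.  Idempotent.
    """
    keep = _CHANNEL_INDEX[color]
    out = np.zeros_like(image.pixels)
    out[:, :, keep] = image.pixels[:, :, keep]
    return RGBImage(out)


def suppress_low_red(
    image: RGBImage, threshold: float
) -> tuple[RGBImage, np.ndarray]:
    """Unify low-red pixels with the background.

    Tissue with no erythema still carries some red value and would be
    mis-counted; pixels whose red value falls below ``threshold`` are set
    to (0, 0, 0) and excluded from the returned boolean foreground mask.
    Threshold 0 keeps every pixel; a threshold above 255 removes all.
    """
    mask = image.red() >= threshold
    out = image.pixels.copy()
    out[~mask] = 0
    return RGBImage(out), mask


def adjust_brightness(image: RGBImage, level: int) -> RGBImage:
    """Rescale exposure by white-balance level.

    Levels follow the high/medium/low convention: 50 doubles every channel
    (high brightness), 100 is the identity (as shot), 200 halves (dark).
    General positive levels scale by 100/level; results are rounded
    half-up and clipped to [0, 255].
    """
    if level <= 0:
        raise ValueError("brightness level must be positive")
    if level == 100:
        return image
    scaled = image.pixels.astype(float) * (100.0 / level)
    return RGBImage(_clip_u8(_round_half_up(scaled)))


def measure_card(
    image: RGBImage, patch_boxes: Sequence[tuple[int, int, int, int]]
) -> ColorCardMeasurement:
    """Average the RGB values inside each patch bounding box.

    Boxes are (x, y, w, h), 0-based pixel units, half-open.
    """
    means = []
    for x, y, w, h in patch_boxes:
        region = image.pixels[y : y + h, x : x + w].astype(float)
        if region.size == 0:
            raise ValueError(f"patch box ({x},{y},{w},{h}) is empty")
        means.append(region.reshape(-1, 3).mean(axis=0))
    return ColorCardMeasurement(np.array(means))
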