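"""Leaf image ingestion and per-channel pixel sampling.

A leaf photograph enters the pipeline either as an RGBA PNG whose background
was made fully transparent during cutout (alpha rule), or as a flat RGB image
shot on a bright matte background, in which case a luminance threshold
separates leaf from background.  All downstream statistics operate on the flat
sequence of masked-pixel gradation levels, one sequence per channel; gray (Y)
is derived with BT.601 luma weights and rounded back to integer levels, which
is what 8-bit image toolboxes do before computing histogram statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError, DegenerateInputError, InputError

#: BT.601 luma weights used for the gray channel.
GRAY_WEIGHTS: Tuple[float, float, float] = (0.2989, 0.5870, 0.1140)

CHANNELS = ("R", "G", "B", "Y")


def round_half_away_from_zero(x):
    """Round to the nearest integer, halves away from zero (MATLAB-style).

    numpy's default rounds halves to even, which would bias gradation
    discretization relative to the reference behaviour.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class LeafImage:
    """A masked 8-bit RGB raster; the unit of analysis.

    ``mask`` is True on leaf pixels.  All four rasters share one shape and
    intensities are integers in [0, 255].
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.red, self.green, self.blue, self.mask)}
        if len(shapes) != 1 or self.red.ndim != 2:
            raise InputError("red/green/blue/mask must share one 2-D shape")
        if self.mask.dtype != np.bool_:
            raise InputError("mask must be boolean")
        for name in ("red", "green", "blue"):
            ch = getattr(self, name)
            if not np.issubdtype(ch.dtype, np.integer):
                raise InputError(f"{name} raster must be integer-typed")
            if ch.dtype != np.uint8 and ch.size and (ch.min() < 0 or ch.max() > 255):
                raise InputError(f"{name} raster has values outside [0, 255]")

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def n_leaf_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PixelSample:
    """Flat sequence of integer gradation levels from the masked pixels of one channel."""

    channel: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InputError(f"unknown channel {self.channel!r}")
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size < 1:
            raise DegenerateInputError("pixel sample must be a non-empty 1-D sequence")

    @property
    def n(self) -> int:
        return int(self.values.size)


def _gray_levels(r: np.ndarray, g: np.ndarray, b: np.ndarray,
                 weights: Tuple[float, float, float] = GRAY_WEIGHTS) -> np.ndarray:
    y = (weights[0] * r.astype(np.float64)
         + weights[1] * g.astype(np.float64)
         + weights[2] * b.astype(np.float64))
    return np.clip(round_half_away_from_zero(y), 0, 255).astype(np.int64)


def load_leaf_image(path, background_rule: str = "alpha", threshold: int = 250,
                    resize: Tuple[int, int] | None = None) -> LeafImage:
    """Read a PNG/JPEG leaf photograph and derive its analysis mask.

    Parameters
    ----------
    path :
        PNG (RGBA or RGB) or JPEG (RGB) file.
    background_rule :
        ``"alpha"`` — leaf pixels are those with alpha > 0 (transparent-background
        cutouts); ``"threshold"`` — leaf pixels are those whose gray level is
        below ``threshold`` (bright matte background).
    threshold :
        Gray-level cut for the threshold rule; background is *brighter* than this.
    resize :
        Optional ``(width, height)`` nearest-neighbour resize applied before
        sampling.  Off by default because resampling perturbs the histogram;
        nearest-neighbour is used so the gradation value set is preserved.
    """
    try:
        img = Image.open(Path(path))
        img.load()
    except (OSError, UnidentifiedImageError) as exc:
        raise InputError(f"cannot read image {path!r}: {exc}") from exc

    if resize is not None:
        img = img.resize(resize, Image.NEAREST)

    if background_rule == "alpha":
        if "A" not in img.getbands():
            raise ConfigurationError(
                "alpha background rule requires an alpha channel; "
                "use background_rule='threshold' for flat RGB/JPEG input")
        arr = np.asarray(img.convert("RGBA"))
        mask = arr[..., 3] > 0
    elif background_rule == "threshold":
        arr = np.asarray(img.convert("RGB"))
        gray = _gray_levels(arr[..., 0], arr[..., 1], arr[..., 2])
        mask = gray < int(threshold)
    else:
        raise ConfigurationError(f"unknown background rule {background_rule!r}")

    if not mask.any():
        raise DegenerateInputError(
            f"mask is empty for {path!r}: no pixel satisfies the {background_rule} rule")

    return LeafImage(red=arr[..., 0].astype(np.uint8),
                     green=arr[..., 1].astype(np.uint8),
                     blue=arr[..., 2].astype(np.uint8),
                     mask=mask)


def to_gray(image: LeafImage, weights: Tuple[float, float, float] = GRAY_WEIGHTS) -> PixelSample:
    """Gray (Y) sample over masked pixels: round(0.2989 R + 0.5870 G + 0.1140 B).

    Rounding is half-away-from-zero and the result is clamped to [0, 255].
    For R = G = B the output equals the common level at every pixel, because
    the weights sum to 0.9999 and 0.0001·255 < 0.5.
    """
    if image.n_leaf_pixels < 1:
        raise DegenerateInputError("image has an empty mask")
    y = _gray_levels(image.red, image.green, image.blue, weights)
    return PixelSample(channel="Y", values=y[image.mask])


def channel_sample(image: LeafImage, channel: str) -> PixelSample:
    """Masked-pixel gradation levels of one channel, in row-major scan order."""
    if image.n_leaf_pixels < 1:
        raise DegenerateInputError("image has an empty mask")
    if channel == "Y":
        return to_gray(image)
    try:
        raster = {"R": image.red, "G": image.green, "B": image.blue}[channel]
    except KeyError:
        raise InputError(f"unknown channel {channel!r}") from None
    return PixelSample(channel=channel, values=raster[image.mask].astype(np.int64))


def save_leaf_png(image: LeafImage, path) -> None:
    """Write the image as an RGBA PNG with background alpha = 0 (lossless round trip)."""
    h, w = image.mask.shape
    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    rgba[..., 0] = image.red
    rgba[..., 1] = image.green
    rgba[..., 2] = image.blue
    rgba[..., 3] = np.where(image.mask, 255, 0)
    Image.fromarray(rgba, mode="RGBA").save(Path(path))


def save_mask_png(image: LeafImage, path) -> None:
    """Write the analysis mask as a 1-bit PNG."""
    Image.fromarray(image.mask).convert("1").save(Path(path))
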