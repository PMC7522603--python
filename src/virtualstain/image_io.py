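"""Reading, writing and intensity preprocessing of microscopy channels.

The pipeline is grayscale-only: a multi-channel input is a stack of
single-channel images.  Every image carries its bit depth (8 or 16) so that
normalization, metrics and TIFF round-trips agree on the full-scale value
``2**bit_depth - 1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image


class FormatError(ValueError):
    """Raised when a file is not a readable grayscale 8/16-bit image."""


_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class ChannelImage:
    """One co-registered grayscale microscopy channel.

    Parameters
    ----------
    pixels
        2-D integer-valued array; values must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16.
    channel_label
        Free-text channel name (e.g. ``"nuclei"``, ``"F-actin"``).
    pixel_size
        Physical pixel size in micrometers, if known.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel_label: str = ""
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError(f"pixels must be a nonzero 2-D grid, got shape {self.pixels.shape}")
        if self.pixels.dtype != _DTYPES[self.bit_depth]:
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > self.full_scale:
                raise ValueError(
                    f"pixel values [{lo}, {hi}] outside [0, {self.full_scale}] for {self.bit_depth}-bit"
                )
            self.pixels = np.round(self.pixels).astype(_DTYPES[self.bit_depth])

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ChannelImage":
        return ChannelImage(self.pixels.copy(), self.bit_depth, self.channel_label, self.pixel_size)


@dataclass
class NormalizedImage:
    """Real-valued image in [-1, 1] together with its source bit depth."""

    pixels: np.ndarray
    source_bit_depth: int = 16
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min() < -1.0 - 1e-12 or self.pixels.max() > 1.0 + 1e-12:
            raise ValueError("normalized pixels must lie in [-1, 1]")


def read_image(path: str | os.PathLike) -> ChannelImage:
    """Read a grayscale 8- or 16-bit TIFF or PNG into a :class:`ChannelImage`.

    Bit depth is inferred from the stored dtype; pixel values are not
    modified.  RGB or other multi-sample files raise :class:`FormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype} (need uint8 or uint16)")
    label = os.path.splitext(os.path.basename(path))[0]
    return ChannelImage(arr, depth, channel_label=label)


def write_image(img: ChannelImage, path: str | os.PathLike, compression: str | None = None) -> None:
    """Write a :class:`ChannelImage` as grayscale TIFF or PNG (8-bit only).

    ``compression`` applies to TIFF only (e.g. ``"lzw"``); default is
    uncompressed.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels, compression=compression)
    elif ext == ".png":
        if img.bit_depth != 8:
            raise FormatError("PNG output is supported for 8-bit images only")
        Image.fromarray(img.pixels).save(path)
    else:
        raise FormatError(f"unsupported output format: {path}")


def normalize(img: ChannelImage) -> NormalizedImage:
    """Linearly map ``[0, 2**bit_depth - 1]`` to ``[-1, 1]``.

    The denominator is the dtype full scale, not the per-image maximum, so
    intensities stay comparable across fields of view.
    """
    x = img.pixels.astype(np.float64) * (2.0 / img.full_scale) - 1.0
    return NormalizedImage(x, img.bit_depth, img.channel_label)


def denormalize(nimg: NormalizedImage) -> ChannelImage:
    """Inverse of :func:`normalize`: map [-1, 1] back to integer intensities.

    Out-of-range values are clipped to the bit range; results are rounded to
    the nearest integer level, so ``denormalize(normalize(img)) == img`` for
    any integer-valued input.
    """
    full = (1 << nimg.source_bit_depth) - 1
    x = (np.asarray(nimg.pixels, dtype=np.float64) + 1.0) * (full / 2.0)
    x = np.clip(np.round(x), 0, full)
    return ChannelImage(x.astype(_DTYPES[nimg.source_bit_depth]), nimg.source_bit_depth,
                        nimg.channel_label)


def equalize_histogram(img: ChannelImage) -> ChannelImage:
    """Global histogram equalization on the integer intensity scale.

    The classic CDF remap: ``v -> round((cdf(v) - cdf_min) / (N - cdf_min) * full)``.
    The remap is monotone non-decreasing, so the rank order of distinct pixel
    values is never inverted.  A constant image has no contrast to equalize
    and is returned unchanged.
    """
    full = img.full_scale
    flat = img.pixels.ravel()
    counts = np.bincount(flat, minlength=full + 1)
    cdf = np.cumsum(counts)
    nz = np.nonzero(counts)[0]
    if nz.size <= 1:  # constant image
        return img.copy()
    cdf_min = cdf[nz[0]]
    n = flat.size
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * full).astype(_DTYPES[img.bit_depth])
    return ChannelImage(lut[flat].reshape(img.shape), img.bit_depth,
                        img.channel_label, img.pixel_size)
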