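"""Grayscale image data model, PNG/TIFF I/O, and classical resamplers.

All algorithms in this package operate on :class:`GrayImage`, a 2-D grid of
intensities normalized to ``[0, 1]``.  Files are read and written at 8- or
16-bit depth; multi-channel inputs are collapsed to luminance (BT.601) on
load.

Resampling conventions
----------------------
* Integer factors ``k >= 1`` are *corner-anchored*: low-resolution pixel
  ``(i, j)`` maps exactly onto high-resolution pixel ``(k*i, k*j)``.  This
  gives low-resolution edge points well-defined positions on the
  high-resolution grid.
* Fractional factors use center-aligned continuous coordinates.
* Nearest-neighbor rounding is half-down (ties pick the smaller index), so
  a 0.5 downscale keeps the top-left sample of every 2x2 block and a 2x
  upscale replicates each pixel.
* Out-of-range samples are handled with replicate (edge-clamp) padding and
  outputs are clipped to ``[0, 1]``.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = ["GrayImage", "read_image", "write_image", "resample", "RESAMPLE_METHODS"]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA_WEIGHTS = np.asarray([0.299, 0.587, 0.114], dtype=np.float64)

_DEPTH_PEAK = {8: 255, 16: 65535}

RESAMPLE_METHODS = ("nearest", "bilinear", "bicubic")
_SPLINE_ORDER = {"bilinear": 1, "bicubic": 3}


@dataclasses.dataclass(frozen=True, eq=False)
class GrayImage:
    """A 2-D grayscale image with intensities in ``[0, 1]``.

    Parameters
    ----------
    pixels
        2-D float array; copied, validated, and made read-only.
    source_depth
        Native bit depth of the originating file (8 or 16); used when the
        image is written back out and when metrics rescale to a native peak.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("zero-sized image")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixels must lie within [0, 1]")
        if self.source_depth not in _DEPTH_PEAK:
            raise ValueError(f"source_depth must be 8 or 16, got {self.source_depth}")
        px = px.copy()
        px.flags.writeable = False
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def allclose(self, other: "GrayImage", atol: float = 0.0) -> bool:
        return self.shape == other.shape and np.allclose(
            self.pixels, other.pixels, rtol=0.0, atol=atol
        )


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a channel axis (if any) with BT.601 luminance weights."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ _LUMA_WEIGHTS
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[..., 0].astype(np.float64)
    raise ValueError(f"unsupported image layout with shape {arr.shape}")


def read_image(path: str | os.PathLike) -> GrayImage:
    """Load a PNG or TIFF file as a normalized grayscale image.

    Multi-channel files are converted with BT.601 luminance weights on the
    native integer scale before normalization to ``[0, 1]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"unsupported format: {path.suffix!r} (expected PNG or TIFF)")
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError("zero-sized image")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == bool:
        arr, depth = arr.astype(np.uint8) * 255, 8
    else:
        raise ValueError(f"unsupported sample type {arr.dtype} (expected uint8/uint16)")
    gray = _to_gray(arr) / _DEPTH_PEAK[depth]
    return GrayImage(np.clip(gray, 0.0, 1.0), source_depth=depth)


def write_image(img: GrayImage, path: str | os.PathLike, depth: int | None = None) -> None:
    """Write ``img`` to PNG or TIFF at the requested bit depth.

    A write/read round trip changes no pixel by more than one quantization
    step (``1/255`` or ``1/65535``).
    """
    path = Path(path)
    if str(path) == "":
        raise ValueError("empty output path")
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"unsupported format: {path.suffix!r} (expected PNG or TIFF)")
    depth = img.source_depth if depth is None else depth
    if depth not in _DEPTH_PEAK:
        raise ValueError(f"depth must be 8 or 16, got {depth}")
    peak = _DEPTH_PEAK[depth]
    quantized = np.rint(img.pixels * peak).astype(np.uint8 if depth == 8 else np.uint16)
    iio.imwrite(path, quantized)


def _output_length(n: int, factor: float) -> int:
    out = int(round(n * factor))
    if out < 1:
        raise ValueError(f"resample factor {factor} collapses dimension {n} to zero")
    return out


def _source_coords(n_out: int, factor: float) -> np.ndarray:
    out = np.arange(n_out, dtype=np.float64)
    if float(factor).is_integer() and factor >= 1:
        return out / factor  # corner-anchored
    return (out + 0.5) / factor - 0.5  # center-aligned


def resample(img: GrayImage, factor: float, method: str = "bilinear") -> GrayImage:
    """Rescale ``img`` by ``factor`` with the given method.

    ``method`` is one of ``nearest``, ``bilinear``, ``bicubic``.  Factor 1 is
    the identity for every method; flat images stay flat.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    if method not in RESAMPLE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {RESAMPLE_METHODS}")
    if factor == 1:
        return img
    h_out = _output_length(img.height, factor)
    w_out = _output_length(img.width, factor)
    px = img.pixels
    if px.min() == px.max():
        # Flat images are exact fixed points of every resampler; spline
        # arithmetic would otherwise leave 1-ulp noise.
        return GrayImage(np.full((h_out, w_out), px.flat[0]), source_depth=img.source_depth)
    rows = _source_coords(h_out, factor)
    cols = _source_coords(w_out, factor)
    if method == "nearest":
        # Half-down rounding: ties go to the smaller index, so integer-factor
        # upscaling replicates pixels and 0.5 downscaling keeps top-left
        # samples of each 2x2 block.
        ri = np.clip(np.ceil(rows - 0.5).astype(np.intp), 0, img.height - 1)
        ci = np.clip(np.ceil(cols - 0.5).astype(np.intp), 0, img.width - 1)
        out = px[np.ix_(ri, ci)]
    else:
        grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
        order = _SPLINE_ORDER[method]
        out = ndimage.map_coordinates(
            px, [grid_r, grid_c], order=order, mode="nearest", prefilter=order > 1
        )
    return GrayImage(np.clip(out, 0.0, 1.0), source_depth=img.source_depth)
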