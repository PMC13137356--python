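"""Shared image types and I/O.

Every stage of the pipeline works on plain 2-D numpy arrays:

* a *gray image* is a ``(H, W)`` ``uint8`` array on the 0-255 scale
  (float arrays are accepted by the texture operators downstream, which
  treat intensities as continuous);
* a *binary mask* is a ``(H, W)`` array of ``{0, 1}`` (``uint8``), stored
  on disk as a single-channel PNG with values ``{0, 255}``.

Coordinates are row-major, 0-based, ``(row, col)`` with the origin at the
top-left corner.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import tifffile

# ITU-R BT.601 luminance weights used for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Map a loaded raster to the 8-bit 0-255 scale."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.rint(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        top = max(int(arr.max()), 255)
        return np.rint(arr.astype(np.float64) / top * 255.0).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.rint(np.clip(arr, 0.0, 255.0)).astype(np.uint8)
    raise ValueError(f"unsupported image dtype: {arr.dtype}")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF image as a 2-D uint8 gray image.

    RGB(A) input is converted with BT.601 luminance; 16-bit input is
    rescaled to 0-255 by max-value division.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {arr.shape[2]}: {path}")
        rgb = arr[..., :3].astype(np.float64)
        if arr.dtype == np.uint16:
            rgb = rgb / 65535.0 * 255.0
        gray = rgb @ _LUMA
        return np.rint(np.clip(gray, 0.0, 255.0)).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}: {path}")
    return _to_uint8(arr)


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a gray image. ``.tif/.tiff`` keeps the array dtype (e.g. float32
    intermediates); other extensions are written as 8-bit PNG."""
    path = os.fspath(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("save_image expects a 2-D array")
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img)
        return
    if img.dtype != np.uint8:
        img = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    iio.imwrite(path, img)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a {0,255} PNG mask as a {0,1} uint8 array."""
    return (load_image(path) > 127).astype(np.uint8)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    save_image(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def as_gray(img: np.ndarray, min_size: int = 1) -> np.ndarray:
    """Validate a 2-D intensity array and return it as float64."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(f"image {img.shape} smaller than required {min_size}x{min_size}")
    return img.astype(np.float64)


def pad_reflect(img: np.ndarray, margin: int) -> np.ndarray:
    """Mirror-pad (reflect-101, edge pixel not repeated) by ``margin`` on all sides."""
    img = np.asarray(img)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return img.copy()
    if margin >= min(img.shape[:2]):
        raise ValueError(f"margin {margin} >= image dimension {min(img.shape[:2])}")
    return np.pad(img, margin, mode="reflect")
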