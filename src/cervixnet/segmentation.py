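"""Morphological lesion segmentation.

Once an image is classified as cancer, its lesion is localized from the
Gabor texture-energy map (or, optionally, the raw image): the map is
Otsu-binarized, and the lesion *boundary* is the morphological gradient —
binary dilation minus binary erosion — of that mask, a band of roughly
twice the structuring-element radius around each component contour.  The
lesion *region* is the hole-filled binary mask.  Dilation treats pixels
beyond the border as background and erosion as foreground (replication
semantics), so a full-frame mask has an empty gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, footprint_rectangle

from .core import as_gray


@dataclass(frozen=True)
class StructuringElement:
    shape: str = "disk"  # "disk" or "square"
    radius: int = 3

    def footprint(self) -> np.ndarray:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.shape == "disk":
            return disk(self.radius)
        if self.shape == "square":
            side = 2 * self.radius + 1
            return footprint_rectangle((side, side))
        raise ValueError(f"unknown structuring element shape {self.shape!r}")


@dataclass
class SegmentationResult:
    boundary: np.ndarray  # {0,1} dilation - erosion band
    region: np.ndarray    # {0,1} hole-filled mask
    source: str = ""


def binarize(img: np.ndarray) -> np.ndarray:
    """Otsu-threshold binary map; foreground = strictly above threshold."""
    img = as_gray(img)
    if np.ptp(img) == 0:
        warnings.warn("constant image: empty foreground", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    return (img > threshold_otsu(img)).astype(np.uint8)


def segment(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> SegmentationResult:
    """Morphological gradient boundary + hole-filled region of a binary mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    m = mask > 0
    fp = se.footprint().astype(bool)
    dil = ndi.binary_dilation(m, structure=fp, border_value=0)
    ero = ndi.binary_erosion(m, structure=fp, border_value=1)
    boundary = (dil & ~ero).astype(np.uint8)
    region = ndi.binary_fill_holes(m).astype(np.uint8)
    return SegmentationResult(boundary=boundary, region=region)


def segment_image(img: np.ndarray, se: StructuringElement = StructuringElement(),
                  source: str = "gci") -> SegmentationResult:
    """Binarize an intensity map and segment it."""
    result = segment(binarize(img), se=se)
    result.source = source
    return result
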