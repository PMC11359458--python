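"""Morphological operators and the two detectors built on them.

Binary erosion/dilation follow the set definitions (fit / hit of the
structuring element), with out-of-bounds pixels treated as background.
Grayscale erosion/dilation are the local min/max over the footprint with
identity-element padding (255 for min, 0 for max).  The two detectors work
on grayscale frames directly: dilation with a disk of radius 4 enlarges
1-px colloids before thresholding; the white top-hat with a disk of radius
2 keeps only bright features smaller than the disk — precisely the
colloids — and removes grains and pore space entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import otsu_scan
from .types import BinaryMask, GrayFrame
from .filters import ResponseImage

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "opening",
    "top_hat",
    "dilation_detect",
    "tophat_detect",
]


@dataclass(frozen=True)
class StructuringElement:
    """Binary probe shape with its origin at the centre cell."""

    footprint: np.ndarray
    kind: str = "custom"

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("structuring element footprint must be a non-empty 2-D binary grid")
        if fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise ValueError("footprint side lengths must be odd (origin at the centre)")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise ValueError("origin cell of the footprint must be set")
        object.__setattr__(self, "footprint", fp)

    @classmethod
    def disk(cls, r: int) -> "StructuringElement":
        """All offsets (dr, dc) with dr^2 + dc^2 <= r^2 (inclusive)."""
        if r < 0:
            raise ValueError("disk radius must be >= 0")
        dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
        return cls(dr**2 + dc**2 <= r**2, kind=f"disk({r})")

    @classmethod
    def square(cls, n: int) -> "StructuringElement":
        if n < 1 or n % 2 == 0:
            raise ValueError("square side must be odd and >= 1")
        return cls(np.ones((n, n), dtype=bool), kind=f"square({n})")

    @classmethod
    def cross(cls) -> "StructuringElement":
        fp = np.zeros((3, 3), dtype=bool)
        fp[1, :] = True
        fp[:, 1] = True
        return cls(fp, kind="cross")


def _is_binary(image) -> bool:
    return isinstance(image, BinaryMask)


def _pix(image) -> np.ndarray:
    return image.pixels if hasattr(image, "pixels") else np.asarray(image)


def erode(image, se: StructuringElement):
    """Erosion: binary = footprint fits inside foreground (out-of-bounds is
    background); grayscale = local minimum with identity (255) padding."""
    pix = _pix(image)
    if _is_binary(image):
        out = ndimage.minimum_filter(pix, footprint=se.footprint, mode="constant", cval=0)
        return BinaryMask(out)
    out = ndimage.minimum_filter(pix, footprint=se.footprint, mode="constant", cval=255)
    return GrayFrame(out, index=getattr(image, "index", 0))


def dilate(image, se: StructuringElement):
    """Dilation: binary = reflected footprint hits foreground; grayscale =
    local maximum over the reflected footprint with identity (0) padding."""
    pix = _pix(image)
    reflected = np.flip(se.footprint)
    out = ndimage.maximum_filter(pix, footprint=reflected, mode="constant", cval=0)
    if _is_binary(image):
        return BinaryMask(out)
    return GrayFrame(out, index=getattr(image, "index", 0))


def opening(image, se: StructuringElement):
    """Erosion followed by dilation with the same element; idempotent."""
    return dilate(erode(image, se), se)


def top_hat(image: GrayFrame, se: StructuringElement) -> ResponseImage:
    """White top-hat: image minus its opening; non-negative everywhere."""
    opened = opening(image, se)
    diff = _pix(image).astype(np.int16) - _pix(opened).astype(np.int16)
    return ResponseImage(diff.astype(float))


def _binarize(values: np.ndarray, post_threshold) -> BinaryMask:
    """Binarize a detector response: parameter-free Otsu by default, or a
    fixed numeric threshold."""
    vals = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    if post_threshold == "otsu" or post_threshold is None:
        res = otsu_scan(np.bincount(vals.ravel(), minlength=256))
        return BinaryMask.from_bool(vals >= res.threshold)
    return BinaryMask.from_bool(values >= float(post_threshold))


def dilation_detect(frame: GrayFrame, r: int = 4, post_threshold="otsu") -> BinaryMask:
    """Grayscale dilation with disk(r), then global binarization.

    Dilation grows each bright spot to a disk, compensating for the poor
    appearance of 1-px colloids before thresholding.
    """
    dilated = dilate(frame, StructuringElement.disk(r))
    return _binarize(dilated.pixels.astype(float), post_threshold)


def tophat_detect(frame: GrayFrame, r: int = 2, post_threshold="otsu") -> BinaryMask:
    """White top-hat with disk(r), then global binarization of the response."""
    resp = top_hat(frame, StructuringElement.disk(r))
    return _binarize(resp.values, post_threshold)
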