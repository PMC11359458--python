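"""Linear-filter detectors: Laplacian stencil and Difference of Gaussians.

A colloid is a 1–2 px bright spot, which is precisely what a high-pass /
band-pass filter amplifies.  The Laplacian uses the negated 4-neighbour
stencil (centre +4) so a bright spot yields a positive central response;
the DoG kernel subtracts two Gaussians that are each renormalized over the
truncated support, making the kernel exactly zero-sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, GrayFrame

__all__ = [
    "FilterKernel",
    "ResponseImage",
    "convolve",
    "laplacian_kernel",
    "laplacian_detect",
    "dog_kernel",
    "dog_detect",
]

DEFAULT_LAPLACIAN_THRESHOLD = 40.0
DEFAULT_DOG_THRESHOLD = 10.0


@dataclass(frozen=True)
class FilterKernel:
    """Small odd-sized kernel with its origin at the geometric centre."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"kernel must be square 2-D, got shape {w.shape}")
        if w.shape[0] % 2 == 0:
            raise ValueError(f"kernel side length must be odd, got {w.shape[0]}")
        object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ResponseImage:
    """Signed real-valued filter response, same shape as the source frame."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_BORDER_MODES = {"replicate": "nearest", "reflect": "reflect", "zero": "constant"}


def convolve(frame: GrayFrame, kernel: FilterKernel, border: str = "replicate") -> ResponseImage:
    """Discrete correlation of the frame with the kernel.

    The border is handled by replicate-edge padding by default.
    """
    if border not in _BORDER_MODES:
        raise ValueError(f"unknown border policy {border!r}")
    pix = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    out = ndimage.correlate(pix.astype(np.float64), kernel.weights, mode=_BORDER_MODES[border])
    return ResponseImage(out)


def laplacian_kernel() -> FilterKernel:
    """Negated 4-neighbour Laplacian stencil (centre-positive)."""
    return FilterKernel(np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=float))


def laplacian_detect(frame: GrayFrame, response_threshold: float = DEFAULT_LAPLACIAN_THRESHOLD) -> BinaryMask:
    """255 where the negated-Laplacian response exceeds the threshold.

    An isolated bright pixel of value v over a zero background yields a
    central response of 4v with four negative side lobes — the bright dot
    with four dark dots around it that identifies a colloid.
    """
    resp = convolve(frame, laplacian_kernel()).values
    return BinaryMask.from_bool(resp > response_threshold)


def dog_kernel(sigma1: float = 0.5, sigma2: float = 2.0, size: int = 3) -> FilterKernel:
    """Difference-of-Gaussians kernel on a size x size lattice.

    Each truncated Gaussian is normalized to sum 1 over the support before
    subtraction, so the band-pass kernel sums to exactly 0 even at
    aggressive truncation (the working 3x3 size truncates the wide
    sigma2=2 Gaussian heavily).
    """
    if not 0 < sigma1 < sigma2:
        raise ValueError(f"need 0 < sigma1 < sigma2, got sigma1={sigma1}, sigma2={sigma2}")
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and >= 1, got {size}")
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = xx**2 + yy**2

    def gauss(sigma):
        g = np.exp(-r2 / (2.0 * sigma**2))  # 1/(2 pi sigma^2) cancels in normalization
        return g / g.sum()

    return FilterKernel(gauss(sigma1) - gauss(sigma2))


def dog_detect(
    frame: GrayFrame,
    sigma1: float = 0.5,
    sigma2: float = 2.0,
    size: int = 3,
    response_threshold: float = DEFAULT_DOG_THRESHOLD,
) -> BinaryMask:
    """Threshold-plus-zero-crossing detection on the DoG response.

    A pixel fires when its response exceeds the threshold AND at least one
    8-neighbour has a response of opposite sign — the zero-crossing that
    marks an extreme local change in brightness.
    """
    resp = convolve(frame, dog_kernel(sigma1, sigma2, size)).values
    foot = np.ones((3, 3), dtype=bool)
    foot[1, 1] = False
    nb_min = ndimage.minimum_filter(resp, footprint=foot, mode="nearest")
    nb_max = ndimage.maximum_filter(resp, footprint=foot, mode="nearest")
    zero_crossing = ((resp > 0) & (nb_min < 0)) | ((resp < 0) & (nb_max > 0))
    return BinaryMask.from_bool((resp > response_threshold) & zero_crossing)
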