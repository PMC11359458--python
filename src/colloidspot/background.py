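"""Motion-based detectors: frame differencing and background subtraction.

These detectors see only intensity *change* between frames, so a colloid
attached to a grain surface — identical position in every frame — is
invisible to them.  That blindness is a property of the method, not a bug,
and is asserted by the test suite.

All differences are absolute differences computed in a signed dtype; the
motion threshold ``T`` is strict (a pixel fires only when the difference
exceeds T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, FrameSequence, GrayFrame

__all__ = [
    "BackgroundModel",
    "two_frame_diff",
    "three_frame_diff",
    "build_background",
    "fdbs_detect",
    "mfd_detect",
]

DEFAULT_MOTION_THRESHOLD = 25


@dataclass(frozen=True)
class BackgroundModel:
    """Static-background estimate: per-pixel temporal median of a sequence."""

    pixels: np.ndarray
    source_frames: tuple[int, ...]


def _pix(frame) -> np.ndarray:
    return frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)


def _absdiff(a, b) -> np.ndarray:
    return np.abs(_pix(a).astype(np.int16) - _pix(b).astype(np.int16))


def _check_shapes(*frames) -> None:
    shapes = {_pix(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frame shapes differ: {sorted(shapes)}")


def two_frame_diff(fn: GrayFrame, fprev: GrayFrame, T: float = DEFAULT_MOTION_THRESHOLD) -> BinaryMask:
    """255 where |f_n - f_{n-1}| > T (strict), else 0."""
    if T < 0:
        raise ValueError("motion threshold T must be >= 0")
    _check_shapes(fn, fprev)
    return BinaryMask.from_bool(_absdiff(fn, fprev) > T)


def three_frame_diff(
    fprev: GrayFrame, fn: GrayFrame, fnext: GrayFrame, T: float = DEFAULT_MOTION_THRESHOLD
) -> BinaryMask:
    """AND of the backward and forward two-frame differences."""
    _check_shapes(fprev, fn, fnext)
    d1 = _absdiff(fn, fprev) > T
    d2 = _absdiff(fnext, fn) > T
    return BinaryMask.from_bool(d1 & d2)


def build_background(seq: FrameSequence) -> BackgroundModel:
    """Per-pixel temporal median over all frames, rounded to nearest integer.

    The camera is fixed, so no frame alignment is performed; the median
    suppresses transient (moving) colloids while retaining grains, pore
    space and attached colloids.
    """
    if len(seq) < 3:
        raise ValueError(f"background model needs >= 3 frames, got {len(seq)}")
    med = np.median(seq.as_stack(), axis=0)
    return BackgroundModel(
        pixels=np.clip(np.rint(med), 0, 255).astype(np.uint8),
        source_frames=tuple(range(len(seq))),
    )


def fdbs_detect(
    A: GrayFrame, B: GrayFrame, bg: BackgroundModel, T: float = DEFAULT_MOTION_THRESHOLD
) -> BinaryMask:
    """Frame differencing plus background subtraction.

    C = |A - B| > T;  D = |A - background| > T;  result = C AND D.
    A is the current frame, B the previous one.
    """
    _check_shapes(A, B, bg)
    C = _absdiff(A, B) > T
    D = _absdiff(A, bg) > T
    return BinaryMask.from_bool(C & D)


def mfd_detect(
    fprev: GrayFrame, ft: GrayFrame, fnext: GrayFrame, T: float = DEFAULT_MOTION_THRESHOLD
) -> BinaryMask:
    """Multi-frame differencing: mean of the three pairwise absolute
    differences of (f_{t-1}, f_t, f_{t+1}), binarized at T (strict)."""
    _check_shapes(fprev, ft, fnext)
    dt1 = _absdiff(ft, fprev)
    dt2 = _absdiff(fnext, fprev)
    dt3 = _absdiff(fnext, ft)
    fd = (dt1 + dt2 + dt3) / 3.0
    return BinaryMask.from_bool(fd > T)
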