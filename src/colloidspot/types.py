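"""Domain types shared by every detector and the evaluation harness.

Conventions
-----------
* Coordinates are ``(row, col)``, 0-based, with pixel centres at integer
  positions.  Image-processing texts often write ``(x, y)``; here ``x``
  maps to ``col`` and ``y`` to ``row``.
* Intensities live on the 8-bit range ``[0, 255]``.  Binary masks use the
  two values ``{0, 255}`` so that a mask is itself a displayable image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError


def _as_u8(pixels, what: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{what} must be a non-empty 2-D grid, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{what} intensities must be integral")
        arr = np.round(arr)
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError(f"{what} intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class GrayFrame:
    """A single 8-bit grayscale frame with its position in a sequence."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pixels", _as_u8(self.pixels, "GrayFrame"))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrameSequence:
    """An ordered stack of same-shaped frames; ``frame_rate`` is metadata only."""

    frames: tuple[GrayFrame, ...]
    frame_rate: float = 10.0

    def __post_init__(self):
        frames = tuple(self.frames)
        if not frames:
            raise FormatError("FrameSequence needs at least one frame")
        shape = frames[0].shape
        for i, f in enumerate(frames):
            if f.shape != shape:
                raise FormatError(
                    f"frame {i} has shape {f.shape}, expected {shape} (mixed frame sizes)"
                )
        # indices must be consecutive from 0; reindex on construction
        frames = tuple(
            f if f.index == i else GrayFrame(f.pixels, index=i) for i, f in enumerate(frames)
        )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> GrayFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_stack(self) -> np.ndarray:
        """(n_frames, H, W) uint8 view of the sequence."""
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class BinaryMask:
    """Foreground/background grid over {0, 255}; the raw output of a detector."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = _as_u8(self.pixels, "BinaryMask")
        bad = ~np.isin(arr, (0, 255))
        if bad.any():
            raise FormatError("BinaryMask values must be exactly 0 or 255")
        object.__setattr__(self, "pixels", arr)

    @classmethod
    def from_bool(cls, fg: np.ndarray) -> "BinaryMask":
        return cls(np.where(np.asarray(fg, dtype=bool), 255, 0).astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels == 255

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask.from_bool(self.foreground & other.foreground)


@dataclass(frozen=True)
class Detection:
    """One detected particle: sub-pixel centroid plus component area."""

    row: float
    col: float
    area: int

    def __post_init__(self):
        if self.area < 1:
            raise FormatError("Detection area must be >= 1")


@dataclass(frozen=True)
class DetectionSet:
    """All detections of one method on one frame."""

    frame_index: int
    detections: tuple[Detection, ...]
    method: str = ""

    def __post_init__(self):
        dets = tuple(self.detections)
        seen = {(d.row, d.col) for d in dets}
        if len(seen) != len(dets):
            raise FormatError("DetectionSet contains detections with identical centroids")
        object.__setattr__(self, "detections", dets)

    def __len__(self) -> int:
        return len(self.detections)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (row, col) centroids."""
        if not self.detections:
            return np.empty((0, 2))
        return np.array([(d.row, d.col) for d in self.detections], dtype=float)


@dataclass
class GroundTruth:
    """True particle centres per frame, with IDs and a moving/attached flag.

    Stored as a DataFrame with columns (frame, particle_id, row, col, attached).
    """

    table: pd.DataFrame = field(default_factory=lambda: GroundTruth.empty_table())

    COLUMNS = ("frame", "particle_id", "row", "col", "attached")

    @staticmethod
    def empty_table() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": pd.Series(dtype=int),
                "particle_id": pd.Series(dtype=int),
                "row": pd.Series(dtype=float),
                "col": pd.Series(dtype=float),
                "attached": pd.Series(dtype=bool),
            }
        )

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"GroundTruth table lacks columns {sorted(missing)}")
        dup = self.table.duplicated(subset=["frame", "particle_id"])
        if dup.any():
            raise FormatError("duplicate particle_id within a frame")

    def frames(self) -> list[int]:
        return sorted(self.table["frame"].unique().tolist())

    def centers(self, frame: int) -> np.ndarray:
        """(n, 2) array of true (row, col) centres present in ``frame``."""
        sub = self.table[self.table["frame"] == frame]
        return sub[["row", "col"]].to_numpy(dtype=float)

    def n_targets(self, frame: int) -> int:
        return int((self.table["frame"] == frame).sum())
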