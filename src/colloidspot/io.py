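"""Readers/writers for image stacks, detection tables and ground truth.

Frames travel as single-page TIFF/PNG files in a directory (lexicographic
order) or as one multi-page TIFF stack.  Detections and ground truth are
plain CSV so that runs are diffable.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError
from .types import Detection, DetectionSet, FrameSequence, GrayFrame, GroundTruth

_FRAME_EXTS = {".png", ".tif", ".tiff"}


def _to_gray_u8(arr: np.ndarray, what: str) -> np.ndarray:
    """Collapse channels by luminance averaging and rescale >8-bit data."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=2)
    if arr.ndim != 2:
        raise FormatError(f"{what}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        peak = arr.max()
        if peak > 255:
            arr = arr * (255.0 / peak)
        arr = np.round(arr)
    return np.clip(arr, 0, 255).astype(np.uint8)


def read_sequence(path, frame_rate: float = 10.0) -> FrameSequence:
    """Load a frame sequence from a TIFF stack or a directory of images."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    if path.is_dir():
        names = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS and p.is_file()
        )
        if not names:
            raise InputError(f"no PNG/TIFF frames found in {path}")
        arrays = [( str(p), _to_gray_u8(iio.imread(p), str(p)) ) for p in names]
    else:
        stack = tifffile.imread(path)
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        arrays = [(f"{path}[{i}]", _to_gray_u8(page, f"{path}[{i}]")) for i, page in enumerate(stack)]
    shape = arrays[0][1].shape
    for name, arr in arrays:
        if arr.shape != shape:
            raise FormatError(f"frame {name} has shape {arr.shape}, expected {shape}")
    frames = tuple(GrayFrame(arr, index=i) for i, (_, arr) in enumerate(arrays))
    return FrameSequence(frames, frame_rate=frame_rate)


def write_sequence(seq: FrameSequence, path) -> None:
    """Write a sequence as a multi-page 8-bit TIFF stack."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.as_stack(), photometric="minisblack")


_DET_HEADER = ["frame", "method", "row", "col", "area"]


def write_detections(sets: list[DetectionSet], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DET_HEADER)
        for ds in sets:
            for d in ds.detections:
                writer.writerow([ds.frame_index, ds.method, repr(float(d.row)), repr(float(d.col)), d.area])


def read_detections(path) -> list[DetectionSet]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    groups: dict[tuple[int, str], list[Detection]] = {}
    order: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header {_DET_HEADER}")
        if [h.strip() for h in header] != _DET_HEADER:
            raise FormatError(f"{path}: bad header {header}, expected {_DET_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame = int(row[0])
                method = row[1]
                det = Detection(row=float(row[2]), col=float(row[3]), area=int(row[4]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            key = (frame, method)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(det)
    return [
        DetectionSet(frame_index=frame, detections=tuple(groups[(frame, method)]), method=method)
        for frame, method in order
    ]


_GT_HEADER = ["frame", "particle_id", "row", "col", "attached"]


def write_ground_truth(truth: GroundTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = truth.table.copy()
    out["attached"] = out["attached"].astype(int)
    out.to_csv(path, index=False, columns=_GT_HEADER)


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse ground-truth CSV: {exc}") from exc
    if table.empty and not set(_GT_HEADER) <= set(table.columns):
        return GroundTruth()
    missing = set(_GT_HEADER) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: ground truth lacks columns {sorted(missing)}")
    table["attached"] = table["attached"].astype(bool)
    return GroundTruth(table[_GT_HEADER].astype({"frame": int, "particle_id": int}))


def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (comments with '#')."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    out: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}{os.linesep}")
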