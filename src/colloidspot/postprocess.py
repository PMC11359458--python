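"""Mask -> object-level detections: connected components, area filter, centroids."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import BinaryMask, Detection, DetectionSet

__all__ = ["connected_components", "extract_detections"]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def _label(mask: BinaryMask, connectivity: int):
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return ndimage.label(mask.foreground, structure=_STRUCTURES[connectivity])


def connected_components(mask: BinaryMask, connectivity: int = 8) -> list[np.ndarray]:
    """Maximal connected foreground components as (n_i, 2) pixel-coordinate
    arrays, ordered by the raster-scan position of each component's first
    pixel (scipy labels components in exactly that order)."""
    labeled, n = _label(mask, connectivity)
    if n == 0:
        return []
    rows, cols = np.nonzero(labeled)
    labels = labeled[rows, cols]
    order = np.argsort(labels, kind="stable")  # nonzero() is raster order within label
    rows, cols, labels = rows[order], cols[order], labels[order]
    counts = np.bincount(labels, minlength=n + 1)[1:]
    splits = np.cumsum(counts)[:-1]
    coords = np.column_stack([rows, cols])
    return [c for c in np.split(coords, splits)]


def extract_detections(
    mask: BinaryMask,
    frame_index: int = 0,
    method: str = "",
    min_area: int = 1,
    max_area: float = np.inf,
    connectivity: int = 8,
) -> DetectionSet:
    """One detection per component with min_area <= area <= max_area.

    The centroid is the unweighted mean of the component's pixel
    coordinates.  Exactly co-centred components (possible for ring-shaped
    responses) are merged into a single detection with summed area, since
    they describe the same object.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if min_area > max_area:
        raise ValueError(f"min_area ({min_area}) > max_area ({max_area})")
    labeled, n = _label(mask, connectivity)
    dets: list[Detection] = []
    if n > 0:
        idx = np.arange(1, n + 1)
        areas = np.bincount(labeled.ravel(), minlength=n + 1)[1:]
        rows, cols = np.nonzero(labeled)
        labels = labeled[rows, cols]
        rsum = np.bincount(labels, weights=rows, minlength=n + 1)[1:]
        csum = np.bincount(labels, weights=cols, minlength=n + 1)[1:]
        keep = (areas >= min_area) & (areas <= max_area)
        by_centroid: dict[tuple[float, float], int] = {}
        for i, a, rs, cs in zip(idx[keep], areas[keep], rsum[keep], csum[keep]):
            key = (rs / a, cs / a)
            if key in by_centroid:
                j = by_centroid[key]
                dets[j] = Detection(row=key[0], col=key[1], area=dets[j].area + int(a))
            else:
                by_centroid[key] = len(dets)
                dets.append(Detection(row=key[0], col=key[1], area=int(a)))
    return DetectionSet(frame_index=frame_index, detections=tuple(dets), method=method)
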