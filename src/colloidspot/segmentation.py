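"""Segmentation-based detectors: 1-D k-means clustering and Otsu thresholding.

Both operate on the intensity histogram alone.  A micromodel frame has
three intensity regions — dark solid grains, mid-gray pore space, bright
colloids — so k-means is run with k=3 and the cluster with the highest
centre is declared the colloid cluster.  Otsu splits the histogram at the
threshold maximizing the between-class variance; foreground is every pixel
at or above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .types import BinaryMask, GrayFrame

__all__ = [
    "ClusterModel",
    "OtsuResult",
    "kmeans_fit",
    "kmeans_detect",
    "otsu_threshold",
    "otsu_detect",
]


@dataclass(frozen=True)
class ClusterModel:
    """Fitted 1-D k-means model: sorted centres, per-sample labels, SSE."""

    k: int
    centers: np.ndarray
    labels: np.ndarray
    sse: float


def _assign(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # nearest centre; ties broken by lowest cluster index (argmin is first-min)
    dist = np.abs(values[:, None] - centers[None, :])
    return np.argmin(dist, axis=1)


def _lloyd(values, weights, centers, epsilon, max_iter):
    """Weighted Lloyd iterations on 1-D data until max centre shift < epsilon."""
    for _ in range(max_iter):
        labels = _assign(values, centers)
        new = centers.copy()
        for j in range(len(centers)):
            sel = labels == j
            wsel = weights[sel]
            if wsel.sum() == 0:
                # empty-cluster repair: re-seed at the sample farthest from its centre
                far = np.argmax(np.abs(values - centers[_assign(values, centers)]))
                new[j] = values[far]
            else:
                new[j] = np.average(values[sel], weights=wsel)
        shift = np.max(np.abs(new - centers))
        centers = new
        if shift < epsilon:
            break
    labels = _assign(values, centers)
    sse = float(np.sum(weights * (values - centers[labels]) ** 2))
    return centers, labels, sse


def kmeans_fit(
    values,
    k: int,
    epsilon: float = 1e-4,
    seed: int | None = None,
    restarts: int = 10,
    max_iter: int = 300,
    weights=None,
) -> ClusterModel:
    """Fit 1-D k-means with random restarts.

    Initial centres are k distinct values sampled uniformly without
    replacement; the restart with the lowest within-cluster sum of squares
    wins.  ``weights`` allows histogram-weighted fitting (each value
    counted ``weights[i]`` times), which is exactly equivalent to fitting
    the expanded sample.
    """
    values = np.asarray(values, dtype=float).ravel()
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        keep = weights > 0
        values, weights = values[keep], weights[keep]
    distinct = np.unique(values)
    if len(distinct) < k:
        raise DegenerateInputError(
            f"need at least k={k} distinct values, got {len(distinct)}"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        init = rng.choice(distinct, size=k, replace=False)
        centers, labels, sse = _lloyd(values, weights, init.astype(float), epsilon, max_iter)
        if best is None or sse < best[2] - 1e-12:
            best = (centers, labels, sse)
    centers, _, sse = best
    centers = np.sort(centers)
    return ClusterModel(k=k, centers=centers, labels=_assign(values, centers), sse=sse)


def kmeans_detect(
    frame: GrayFrame,
    k: int = 3,
    seed: int | None = 0,
    epsilon: float = 1e-4,
    restarts: int = 10,
) -> BinaryMask:
    """Cluster pixel intensities into k groups; the highest-centre cluster
    is the colloid cluster and becomes the mask foreground.

    Internally fits on the 256-bin histogram (weighted k-means), which is
    identical to clustering the raw pixel list for 8-bit data.
    """
    counts = np.bincount(frame.pixels.ravel(), minlength=256).astype(float)
    present = np.flatnonzero(counts)
    model = kmeans_fit(
        present.astype(float), k=k, epsilon=epsilon, seed=seed, restarts=restarts,
        weights=counts[present],
    )
    # map every intensity value to its cluster, then pick the top cluster
    labels_by_value = np.full(256, -1, dtype=int)
    labels_by_value[present] = model.labels
    top = model.k - 1  # centres are sorted ascending
    return BinaryMask.from_bool(labels_by_value[frame.pixels] == top)


@dataclass(frozen=True)
class OtsuResult:
    """Otsu scan: optimal threshold plus the full diagnostic curves."""

    threshold: int
    variance_curve: np.ndarray  # Var(T) for T = 0..255
    histogram: np.ndarray       # H(i), counts
    cdf: np.ndarray             # C(i), cumulative fraction
    mean: float                 # global mean intensity


def otsu_scan(counts: np.ndarray) -> OtsuResult:
    """Between-class variance scan over all 256 thresholds of a histogram.

    Classes are background = {i < T} and foreground = {i >= T};
    Var(T) = P0(T) * P1(T) * (m0(T) - m1(T))^2, defined as 0 whenever
    either class is empty.  Ties in the argmax go to the smallest T.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError("Otsu needs at least 2 distinct intensity values")
    i = np.arange(256, dtype=float)
    cdf = np.cumsum(counts) / total
    mean = float(np.sum(i * counts) / total)
    # cumulative moments for background class {0..T-1}
    w0 = np.concatenate([[0.0], np.cumsum(counts)[:-1]]) / total       # P0(T)
    s0 = np.concatenate([[0.0], np.cumsum(i * counts)[:-1]]) / total   # sum i*H(i)/N for i<T
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(w0 > 0, s0 / w0, 0.0)
        m1 = np.where(w1 > 0, (mean - s0) / w1, 0.0)
    var = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (m0 - m1) ** 2, 0.0)
    t_opt = int(np.argmax(var))  # first maximum = smallest T
    return OtsuResult(threshold=t_opt, variance_curve=var, histogram=counts, cdf=cdf, mean=mean)


def otsu_threshold(frame: GrayFrame) -> OtsuResult:
    """Otsu threshold of a frame (see :func:`otsu_scan`)."""
    counts = np.bincount(frame.pixels.ravel(), minlength=256)
    return otsu_scan(counts)


def otsu_detect(frame: GrayFrame) -> BinaryMask:
    """Foreground = pixels at or above the Otsu threshold."""
    res = otsu_threshold(frame)
    return BinaryMask.from_bool(frame.pixels >= res.threshold)
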