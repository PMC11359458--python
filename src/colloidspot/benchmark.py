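"""Run detectors over a sequence and score them against ground truth.

``run_benchmark`` executes every detector on each interior frame of a
sequence (frame-differencing methods need both temporal neighbours, so the
first and last frames are never evaluated), converts masks to object-level
detections, matches them to ground truth, aggregates Precision / Recall /
F-measure / TCR per method, and ranks the eight single methods with the
Friedman test plus Holm-corrected pairwise comparisons on the per-frame
F-measures.  The ensemble (majority vote of top-hat, DoG and k-means) is
scored alongside but excluded from the ranking.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .background import build_background, fdbs_detect, mfd_detect, three_frame_diff, two_frame_diff
from .ensemble import majority_vote, majority_vote_masks
from .errors import InputError
from .evaluation import (
    RankTable,
    MetricsReport,
    aggregate,
    frame_metrics,
    friedman_test,
    match_detections,
)
from .filters import dog_detect, laplacian_detect
from .morphology import dilation_detect, tophat_detect
from .postprocess import extract_detections
from .segmentation import kmeans_detect, otsu_detect
from .types import DetectionSet, FrameSequence, GroundTruth

__all__ = [
    "DetectorConfig",
    "BenchmarkResult",
    "SINGLE_METHODS",
    "ALL_METHODS",
    "detect_frame",
    "detect_sequence",
    "run_benchmark",
    "write_benchmark",
]

SINGLE_METHODS = ("kmeans", "otsu", "fdbs", "mfd", "laplacian", "dog", "dilation", "tophat")
ALL_METHODS = SINGLE_METHODS + ("ensemble",)
_NEEDS_NEIGHBOURS = {"fdbs", "mfd"}


@dataclass(frozen=True)
class DetectorConfig:
    """Every tunable knob of the detection/evaluation pipeline."""

    # segmentation
    kmeans_k: int = 3
    kmeans_seed: int = 0
    kmeans_restarts: int = 10
    kmeans_epsilon: float = 1e-4
    # background / motion
    bg_threshold: float = 25.0
    # filters
    dog_sigma1: float = 0.5
    dog_sigma2: float = 2.0
    dog_size: int = 3
    dog_threshold: float = 10.0
    laplacian_threshold: float = 40.0
    # morphology
    dilation_radius: int = 4
    tophat_radius: int = 2
    morph_post_threshold: str | float = "otsu"
    # object extraction
    connectivity: int = 8
    min_area: int = 1
    max_area: float = 200.0
    # evaluation
    match_tol: float = 3.0
    alpha: float = 0.05
    # ensemble
    ensemble_methods: tuple[str, str, str] = ("tophat", "dog", "kmeans")
    ensemble_vote_radius: float = 5.0
    ensemble_mode: str = "object"  # or "pixel"

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def detect_frame(method: str, seq: FrameSequence, t: int, cfg: DetectorConfig, bg=None):
    """Binary mask of one single method on frame ``t`` of a sequence.

    Returns ``None`` for boundary frames of methods that need temporal
    neighbours (no padding is invented there).
    """
    frame = seq[t]
    if method == "kmeans":
        return kmeans_detect(
            frame, k=cfg.kmeans_k, seed=cfg.kmeans_seed,
            epsilon=cfg.kmeans_epsilon, restarts=cfg.kmeans_restarts,
        )
    if method == "otsu":
        return otsu_detect(frame)
    if method == "laplacian":
        return laplacian_detect(frame, response_threshold=cfg.laplacian_threshold)
    if method == "dog":
        return dog_detect(
            frame, sigma1=cfg.dog_sigma1, sigma2=cfg.dog_sigma2,
            size=cfg.dog_size, response_threshold=cfg.dog_threshold,
        )
    if method == "dilation":
        return dilation_detect(frame, r=cfg.dilation_radius, post_threshold=cfg.morph_post_threshold)
    if method == "tophat":
        return tophat_detect(frame, r=cfg.tophat_radius, post_threshold=cfg.morph_post_threshold)
    if method in ("fd2", "fd3", "fdbs", "mfd"):
        if t == 0 or (method in ("fd3", "mfd") and t == len(seq) - 1):
            return None
        if method == "fd2":
            return two_frame_diff(frame, seq[t - 1], T=cfg.bg_threshold)
        if method == "fd3":
            return three_frame_diff(seq[t - 1], frame, seq[t + 1], T=cfg.bg_threshold)
        if method == "fdbs":
            bg = bg if bg is not None else build_background(seq)
            return fdbs_detect(frame, seq[t - 1], bg, T=cfg.bg_threshold)
        return mfd_detect(seq[t - 1], frame, seq[t + 1], T=cfg.bg_threshold)
    raise ValueError(f"unknown method {method!r}")


def _extract(mask, t, method, cfg: DetectorConfig) -> DetectionSet:
    return extract_detections(
        mask, frame_index=t, method=method,
        min_area=cfg.min_area, max_area=cfg.max_area, connectivity=cfg.connectivity,
    )


def ensemble_detections(seq: FrameSequence, t: int, cfg: DetectorConfig, bg=None) -> DetectionSet:
    """Majority-vote detections of the configured three-method ensemble."""
    masks = [detect_frame(m, seq, t, cfg, bg=bg) for m in cfg.ensemble_methods]
    if any(m is None for m in masks):
        raise InputError(f"ensemble constituents unavailable on frame {t}")
    if cfg.ensemble_mode == "pixel":
        fused = majority_vote_masks(masks)
        return _extract(fused, t, "ensemble", cfg)
    sets = [_extract(m, t, name, cfg) for m, name in zip(masks, cfg.ensemble_methods)]
    return majority_vote(sets, vote_radius=cfg.ensemble_vote_radius)


def detect_sequence(seq: FrameSequence, method: str, cfg: DetectorConfig | None = None) -> list[DetectionSet]:
    """Object-level detections of one method (or the ensemble) on every
    frame it is defined on."""
    cfg = cfg or DetectorConfig()
    bg = build_background(seq) if (method == "fdbs" and len(seq) >= 3) else None
    out = []
    for t in range(len(seq)):
        if method == "ensemble":
            out.append(ensemble_detections(seq, t, cfg, bg=bg))
            continue
        mask = detect_frame(method, seq, t, cfg, bg=bg)
        if mask is not None:
            out.append(_extract(mask, t, method, cfg))
    return out


@dataclass
class BenchmarkResult:
    metrics: MetricsReport
    ranks: RankTable | None
    frames_evaluated: list[int]
    config: DetectorConfig


def run_benchmark(
    seq: FrameSequence,
    truth: GroundTruth,
    cfg: DetectorConfig | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
) -> BenchmarkResult:
    """Score every requested method on the interior frames of ``seq``.

    All methods are evaluated on the same frames (1 .. n-2) so the
    Friedman blocks are matched.  The rank table is computed over the
    single methods only and omitted when fewer than two are present.
    """
    cfg = cfg or DetectorConfig()
    if len(seq) < 3:
        raise InputError("benchmark needs at least 3 frames (interior frames are evaluated)")
    frames_eval = list(range(1, len(seq) - 1))
    have = set(truth.frames())
    missing = [t for t in frames_eval if t not in have]
    if missing:
        raise InputError(f"ground truth missing for evaluated frames {missing}")
    bg = build_background(seq)
    rows = []
    for method in methods:
        for t in frames_eval:
            if method == "ensemble":
                dets = ensemble_detections(seq, t, cfg, bg=bg)
            else:
                mask = detect_frame(method, seq, t, cfg, bg=bg)
                dets = _extract(mask, t, method, cfg)
            counts = match_detections(dets, truth.centers(t), tol=cfg.match_tol)
            row = {"frame": t, "method": method, "tp": counts.tp, "fp": counts.fp, "fn": counts.fn}
            row.update(frame_metrics(counts))
            rows.append(row)
    report = aggregate(pd.DataFrame(rows))
    singles = [m for m in methods if m != "ensemble"]
    ranks = None
    if len(singles) >= 2 and len(frames_eval) >= 2:
        ranks = friedman_test(report.score_matrix("f_measure", methods=singles), alpha=cfg.alpha)
    return BenchmarkResult(metrics=report, ranks=ranks, frames_evaluated=frames_eval, config=cfg)


def write_benchmark(result: BenchmarkResult, outdir, manifest_extra: dict | None = None) -> None:
    """Write metrics.csv, ranks.csv, holm.csv, report.txt and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.summary.to_csv(outdir / "metrics.csv")
    result.metrics.per_frame.to_csv(outdir / "per_frame.csv", index=False)
    lines = [result.metrics.to_text(), ""]
    if result.ranks is not None:
        result.ranks.mean_ranks.to_frame().to_csv(outdir / "ranks.csv")
        result.ranks.pairwise.to_csv(outdir / "holm.csv", index=False)
        lines += [
            f"Friedman chi-square = {result.ranks.statistic:.4f}, "
            f"p = {result.ranks.pvalue:.3g} over {result.ranks.n_blocks} frames",
            "mean ranks (1 = best):",
            result.ranks.mean_ranks.to_string(),
        ]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    manifest = {
        "package_version": _pkg_version,
        "config": result.config.asdict(),
        "frames_evaluated": result.frames_evaluated,
    }
    manifest.update(manifest_extra or {})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
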