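"""Majority-vote ensemble over three detectors.

Each of three methods decides, per candidate colloid, "detect" or "not
detect"; the ensemble keeps a colloid when at least two methods agree on
it.  Detections from different methods are identified as the same colloid
when their centroids fall within ``vote_radius`` pixels (object-level
mode, the default).  A pixel-level mode — foreground where at least two of
the three masks are foreground — is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, Detection, DetectionSet

__all__ = ["VoteCluster", "majority_vote", "majority_vote_masks"]

DEFAULT_VOTE_RADIUS = 5.0


@dataclass(frozen=True)
class VoteCluster:
    """Cross-method group of detections believed to be one colloid."""

    members: tuple[tuple[str, Detection], ...]  # (method, detection), <= 1 per method
    centroid: tuple[float, float]

    @property
    def support(self) -> int:
        return len(self.members)


def _dist(a: Detection, b: Detection) -> float:
    return float(np.hypot(a.row - b.row, a.col - b.col))


def _cluster_centroid(members) -> tuple[float, float]:
    rows = [d.row for _, d in members]
    cols = [d.col for _, d in members]
    return (float(np.mean(rows)), float(np.mean(cols)))


def vote_clusters(sets: list[DetectionSet], vote_radius: float = DEFAULT_VOTE_RADIUS) -> list[VoteCluster]:
    """Greedy cross-method clustering of three DetectionSets.

    Repeatedly take the unclustered cross-method pair with the smallest
    centroid distance <= vote_radius (ties broken by method-name order,
    then detection order), then grow the pair with the nearest remaining
    third-method detection lying within vote_radius of the cluster
    centroid and of each member.  Detections left over become support-1
    singleton clusters.  The result is invariant under permutation of the
    input sets because methods are ordered by name internally.
    """
    if len(sets) != 3:
        raise ValueError(f"majority vote needs exactly 3 DetectionSets, got {len(sets)}")
    frames = {s.frame_index for s in sets}
    if len(frames) != 1:
        raise ValueError(f"DetectionSets disagree on frame index: {sorted(frames)}")
    if vote_radius <= 0:
        raise ValueError("vote_radius must be > 0")
    names = [s.method for s in sets]
    if len(set(names)) != 3:
        raise ValueError("the 3 DetectionSets must come from 3 distinct methods")
    ordered = sorted(sets, key=lambda s: s.method)

    # candidate pool: (method, index-within-method, Detection)
    pool = {(s.method, i): d for s in ordered for i, d in enumerate(s.detections)}
    pairs = []
    keys = sorted(pool)
    for ai, ka in enumerate(keys):
        for kb in keys[ai + 1 :]:
            if ka[0] == kb[0]:
                continue
            d = _dist(pool[ka], pool[kb])
            if d <= vote_radius:
                pairs.append((d, ka, kb))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    used: set[tuple[str, int]] = set()
    clusters: list[VoteCluster] = []
    for d, ka, kb in pairs:
        if ka in used or kb in used:
            continue
        members = [(ka[0], pool[ka]), (kb[0], pool[kb])]
        used.update((ka, kb))
        centroid = _cluster_centroid(members)
        third_method = ({"%s" % s.method for s in ordered} - {ka[0], kb[0]}).pop()
        best = None
        for key in keys:
            if key[0] != third_method or key in used:
                continue
            det = pool[key]
            dc = float(np.hypot(det.row - centroid[0], det.col - centroid[1]))
            if dc <= vote_radius and all(_dist(det, m) <= vote_radius for _, m in members):
                if best is None or dc < best[0]:
                    best = (dc, key)
        if best is not None:
            used.add(best[1])
            members.append((best[1][0], pool[best[1]]))
            centroid = _cluster_centroid(members)
        clusters.append(VoteCluster(members=tuple(sorted(members, key=lambda m: m[0])), centroid=centroid))
    for key in keys:
        if key not in used:
            clusters.append(VoteCluster(members=((key[0], pool[key]),), centroid=(pool[key].row, pool[key].col)))
    return clusters


def majority_vote(
    sets: list[DetectionSet],
    vote_radius: float = DEFAULT_VOTE_RADIUS,
    method: str = "ensemble",
) -> DetectionSet:
    """Fused detections supported by >= 2 of the 3 methods.

    The fused centroid is the unweighted mean of the member centroids and
    the fused area the sum of member areas; support-1 singletons are
    dropped (two methods voted "not to detect").
    """
    clusters = vote_clusters(sets, vote_radius=vote_radius)
    dets = [
        Detection(
            row=c.centroid[0],
            col=c.centroid[1],
            area=int(sum(d.area for _, d in c.members)),
        )
        for c in clusters
        if c.support >= 2
    ]
    return DetectionSet(frame_index=sets[0].frame_index, detections=tuple(dets), method=method)


def majority_vote_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Pixel-level vote: foreground where >= 2 of the 3 masks are foreground."""
    if len(masks) != 3:
        raise ValueError(f"pixel vote needs exactly 3 masks, got {len(masks)}")
    votes = sum(m.foreground.astype(np.uint8) for m in masks)
    return BinaryMask.from_bool(votes >= 2)
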