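"""Detection scoring and nonparametric method comparison.

Matching follows the one-target/one-detection discipline: a greedy
ascending-distance one-to-one assignment between detections and
ground-truth centres (tolerance in pixels).  Each target can absorb only
one detection, so duplicate detections near an already-matched target
count as false alarms, and a single merged detection spanning two targets
scores one TP and leaves the rest missed.

Metrics: Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = harmonic mean,
and the Target-to-Clutter Ratio TCR = DT/(DT+MT+FA) with DT=TP, MT=FN,
FA=FP — a single score penalizing both misses and false alarms.

Method comparison uses the Friedman rank test across frames (blocks) with
Holm's step-down correction on all pairwise post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import UndefinedMetricError
from .types import DetectionSet

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RankTable",
    "match_detections",
    "precision",
    "recall",
    "f_measure",
    "tcr",
    "frame_metrics",
    "aggregate",
    "friedman_test",
    "holm_adjust",
]

DEFAULT_MATCH_TOL = 3.0
METRIC_NAMES = ("precision", "recall", "f_measure", "tcr")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN of one frame; DT/FA/MT are the target-detection aliases."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def dt(self) -> int:
        return self.tp

    @property
    def fa(self) -> int:
        return self.fp

    @property
    def mt(self) -> int:
        return self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_detections(dets: DetectionSet | np.ndarray, truth_centers: np.ndarray, tol: float = DEFAULT_MATCH_TOL) -> ConfusionCounts:
    """Greedy one-to-one matching of detections to true centres.

    Pairs are accepted in ascending centroid distance while both endpoints
    are unmatched and the distance is <= tol.  Unmatched detections are
    FPs, unmatched targets FNs.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be > 0")
    pts = dets.centroids() if isinstance(dets, DetectionSet) else np.asarray(dets, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth_centers, dtype=float).reshape(-1, 2)
    nd, nt = len(pts), len(truth)
    if nd == 0 or nt == 0:
        return ConfusionCounts(tp=0, fp=nd, fn=nt)
    dist = cdist(pts, truth)
    order = np.argsort(dist, axis=None, kind="stable")
    det_used = np.zeros(nd, dtype=bool)
    tgt_used = np.zeros(nt, dtype=bool)
    tp = 0
    for flat in order:
        i, j = divmod(int(flat), nt)
        if dist[i, j] > tol:
            break
        if det_used[i] or tgt_used[j]:
            continue
        det_used[i] = tgt_used[j] = True
        tp += 1
    return ConfusionCounts(tp=tp, fp=nd - tp, fn=nt - tp)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when there are no detections (0/0 convention)."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no targets (0/0 convention)."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def tcr(c: ConfusionCounts) -> float:
    """DT / (DT + MT + FA).  Undefined (raises) when nothing exists or is
    predicted, since the frame then carries no information."""
    denom = c.dt + c.mt + c.fa
    if denom == 0:
        raise UndefinedMetricError("TCR undefined: no targets and no detections")
    return c.dt / denom


def frame_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "precision": precision(c),
        "recall": recall(c),
        "f_measure": f_measure(c),
        "tcr": tcr(c),
    }


@dataclass
class MetricsReport:
    """Per-frame metric rows plus the per-method mean (± population std) table."""

    per_frame: pd.DataFrame  # columns: frame, method, tp, fp, fn, precision, recall, f_measure, tcr
    summary: pd.DataFrame = field(init=False)  # index: method; columns: <metric>_mean, <metric>_std

    def __post_init__(self):
        rows = {}
        for method, grp in self.per_frame.groupby("method", sort=False):
            row = {}
            for m in METRIC_NAMES:
                vals = grp[m].to_numpy(dtype=float)
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_std"] = float(vals.std(ddof=0))
            rows[method] = row
        self.summary = pd.DataFrame.from_dict(rows, orient="index")
        self.summary.index.name = "method"

    def score_matrix(self, metric: str = "f_measure", methods: list[str] | None = None) -> pd.DataFrame:
        """methods x frames matrix of one per-frame metric."""
        mat = self.per_frame.pivot(index="method", columns="frame", values=metric)
        if methods is not None:
            mat = mat.loc[methods]
        return mat

    def to_text(self) -> str:
        """Average-results table: one row per method, mean (± std) per metric."""
        lines = [f"{'method':<12}" + "".join(f"{m:>22}" for m in METRIC_NAMES)]
        for method, row in self.summary.iterrows():
            cells = "".join(
                f"{row[f'{m}_mean']:>13.4f} (±{row[f'{m}_std']:.3f})" for m in METRIC_NAMES
            )
            lines.append(f"{method:<12}{cells}")
        return "\n".join(lines)


def aggregate(per_frame: pd.DataFrame) -> MetricsReport:
    """Aggregate per-frame metric rows into a MetricsReport.

    Metrics are computed per frame FIRST and then averaged (arithmetic
    mean, population standard deviation), so the mean F-measure need not
    equal the harmonic mean of the mean precision and recall.
    """
    if per_frame.empty:
        raise ValueError("aggregate needs at least one per-frame row")
    return MetricsReport(per_frame=per_frame.reset_index(drop=True))


@dataclass
class RankTable:
    """Friedman mean ranks, test statistic/p-value, and Holm pairwise table."""

    mean_ranks: pd.Series          # per-method mean rank, 1 = best (highest score)
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame         # method_a, method_b, z, p_raw, p_holm, reject
    alpha: float
    n_blocks: int


def _friedman_ranks(scores: np.ndarray) -> np.ndarray:
    """Within-block ranks, 1 = best = highest score; ties get average ranks."""
    # rankdata ranks ascending, so rank the negated scores
    return np.apply_along_axis(stats.rankdata, 0, -scores)


def friedman_test(scores, alpha: float = 0.05) -> RankTable:
    """Friedman rank test on a methods x frames score matrix.

    Uses the tie-corrected chi-square statistic with k-1 degrees of
    freedom, followed by pairwise rank-difference z-tests whose two-sided
    p-values are Holm-adjusted.
    """
    if isinstance(scores, pd.DataFrame):
        methods = list(scores.index)
        mat = scores.to_numpy(dtype=float)
    else:
        mat = np.asarray(scores, dtype=float)
        methods = [f"method_{i}" for i in range(mat.shape[0])]
    k, n = mat.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >= 2 methods and >= 2 frames, got {k} x {n}")
    ranks = _friedman_ranks(mat)                      # k x n
    mean_ranks = ranks.mean(axis=1)
    # tie-corrected chi-square: (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C),
    # A = sum of squared ranks, C = n k (k+1)^2 / 4; reduces to the classic
    # 12/(nk(k+1)) sum R_j^2 - 3n(k+1) when there are no ties
    rank_sums = ranks.sum(axis=1)
    num = (k - 1) * float(np.sum((rank_sums - n * (k + 1) / 2.0) ** 2))
    den = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    statistic = num / den if den > 0 else 0.0
    pvalue = float(stats.chi2.sf(statistic, df=k - 1))

    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"method_a": methods[i], "method_b": methods[j], "z": z, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    adj, rej = holm_adjust(pairwise["p_raw"].to_numpy(), alpha=alpha)
    pairwise["p_holm"] = adj
    pairwise["reject"] = rej
    pairwise = pairwise.sort_values("p_raw", kind="stable").reset_index(drop=True)
    return RankTable(
        mean_ranks=pd.Series(mean_ranks, index=methods, name="mean_rank").sort_values(kind="stable"),
        statistic=float(statistic),
        pvalue=pvalue,
        pairwise=pairwise,
        alpha=alpha,
        n_blocks=n,
    )


def holm_adjust(pvalues, alpha: float = 0.05):
    """Holm step-down adjusted p-values and rejection flags.

    adjusted p_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending-sorted raw p-values; reject while adjusted <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return adjusted, reject
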