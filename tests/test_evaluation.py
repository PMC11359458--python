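"""Matching rules, detection metrics, aggregation, Friedman and Holm."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import colloidspot as cs
from colloidspot.errors import UndefinedMetricError
from colloidspot.evaluation import frame_metrics


def counts(tp, fp, fn):
    return cs.ConfusionCounts(tp=tp, fp=fp, fn=fn)


class TestMatching:
    def test_exact_hits(self):
        truth = np.array([[5.0, 5.0], [20.0, 20.0], [40.0, 8.0]])
        c = cs.match_detections(truth.copy(), truth, tol=3)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_duplicate_detection_near_one_target_is_false_alarm(self):
        truth = np.array([[10.0, 10.0]])
        dets = np.array([[10.0, 10.0], [11.0, 10.0]])
        c = cs.match_detections(dets, truth, tol=3)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_merged_detection_spanning_two_targets(self):
        truth = np.array([[10.0, 10.0], [10.0, 13.0]])
        dets = np.array([[10.0, 11.0]])  # one detection between two targets
        c = cs.match_detections(dets, truth, tol=3)
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_conservation_laws(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(0, 100, size=(8, 2))
        dets = rng.uniform(0, 100, size=(5, 2))
        c = cs.match_detections(dets, truth, tol=4)
        assert c.tp + c.fn == len(truth)
        assert c.tp + c.fp == len(dets)

    @pytest.mark.parametrize("trial", range(8))
    def test_greedy_matches_exhaustive_assignment_on_separated_points(self, trial):
        """On constellations whose targets are far apart relative to the
        tolerance, greedy matching attains the maximum-cardinality
        assignment found by brute force."""
        rng = np.random.default_rng(11 + trial)
        n = int(rng.integers(2, 6))
        truth = np.array([[30.0 * i, 30.0 * rng.integers(0, 5)] for i in range(n)])
        dets = []
        for t in truth:
            if rng.random() < 0.7:
                dets.append(t + rng.uniform(-2, 2, 2))
            if rng.random() < 0.3:
                dets.append(t + rng.uniform(8, 12, 2))  # clutter outside tol
        dets = np.array(dets) if dets else np.empty((0, 2))
        c = cs.match_detections(dets, truth, tol=3)
        best = 0
        m = min(len(dets), len(truth))
        for k in range(m + 1):
            for dsub in itertools.permutations(range(len(dets)), k):
                for tsub in itertools.combinations(range(len(truth)), k):
                    ok = all(
                        np.linalg.norm(dets[d] - truth[t]) <= 3
                        for d, t in zip(dsub, tsub)
                    )
                    if ok:
                        best = max(best, k)
        assert c.tp == best


class TestMetrics:
    def test_perfect_counts(self):
        c = counts(1, 0, 0)
        assert cs.precision(c) == cs.recall(c) == cs.f_measure(c) == cs.tcr(c) == 1.0

    def test_f_measure_harmonic_mean(self):
        c = counts(1, 0, 1)  # P=1, R=0.5
        assert cs.f_measure(c) == pytest.approx(2 / 3)

    def test_zero_over_zero_convention(self):
        c = counts(0, 0, 5)
        assert cs.precision(c) == 0.0 and cs.recall(c) == 0.0 and cs.f_measure(c) == 0.0

    def test_tcr_known_values(self):
        assert cs.tcr(counts(81, 0, 0)) == 1.0
        assert cs.tcr(counts(0, 2, 3)) == 0.0
        with pytest.raises(UndefinedMetricError):
            cs.tcr(counts(0, 0, 0))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_tcr_bounded_by_precision_and_recall(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        c = counts(tp, fp, fn)
        assert cs.tcr(c) <= min(cs.precision(c), cs.recall(c)) + 1e-12
        assert 0.0 <= cs.tcr(c) <= cs.f_measure(c) + 1e-12 <= 1.0 + 1e-12

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_f_symmetric_in_precision_recall(self, tp, fp, fn):
        assert cs.f_measure(counts(tp, fp, fn)) == pytest.approx(
            cs.f_measure(counts(tp, fn, fp))
        )

    def test_f_is_one_iff_perfect(self):
        assert cs.f_measure(counts(7, 0, 0)) == 1.0
        assert cs.f_measure(counts(7, 1, 0)) < 1.0
        assert cs.f_measure(counts(7, 0, 1)) < 1.0


class TestAggregate:
    def _rows(self, values, method="m"):
        rows = []
        for t, f in enumerate(values):
            rows.append(
                {"frame": t, "method": method, "tp": 1, "fp": 0, "fn": 0,
                 "precision": f, "recall": f, "f_measure": f, "tcr": f}
            )
        return pd.DataFrame(rows)

    def test_single_frame_mean_and_zero_std(self):
        rep = cs.aggregate(self._rows([0.8]))
        assert rep.summary.loc["m", "f_measure_mean"] == 0.8
        assert rep.summary.loc["m", "f_measure_std"] == 0.0

    def test_two_frames_population_std(self):
        rep = cs.aggregate(self._rows([0.8, 1.0]))
        assert rep.summary.loc["m", "f_measure_mean"] == pytest.approx(0.9)
        assert rep.summary.loc["m", "f_measure_std"] == pytest.approx(0.1)

    def test_mean_f_need_not_be_harmonic_mean_of_mean_p_and_r(self):
        # metrics averaged per frame first: the summary F can differ from
        # the F of the summary P and R
        rows = pd.DataFrame(
            [
                {"frame": 0, "method": "m", "tp": 9, "fp": 0, "fn": 1,
                 **frame_metrics(counts(9, 0, 1))},
                {"frame": 1, "method": "m", "tp": 5, "fp": 5, "fn": 0,
                 **frame_metrics(counts(5, 5, 0))},
            ]
        )
        rep = cs.aggregate(rows)
        p, r = rep.summary.loc["m", "precision_mean"], rep.summary.loc["m", "recall_mean"]
        f_of_means = 2 * p * r / (p + r)
        assert rep.summary.loc["m", "f_measure_mean"] != pytest.approx(f_of_means, abs=1e-6)


class TestFriedman:
    def test_full_ties_mean_rank(self):
        mat = np.ones((3, 5))
        table = cs.friedman_test(mat)
        np.testing.assert_allclose(table.mean_ranks.to_numpy(), 2.0)

    def test_hand_computed_strict_ordering(self):
        # 3 methods x 4 frames, A > B > C in every frame
        mat = np.array([[3.0, 3, 3, 3], [2, 2, 2, 2], [1, 1, 1, 1]])
        table = cs.friedman_test(mat)
        np.testing.assert_allclose(
            table.mean_ranks.sort_index().to_numpy(), [1.0, 2.0, 3.0]
        )
        assert table.statistic == pytest.approx(8.0)
        assert table.pvalue == pytest.approx(float(stats.chi2.sf(8.0, df=2)))

    def test_ranks_sum_to_k_k_plus_1_over_2(self):
        rng = np.random.default_rng(2)
        mat = rng.random((6, 9))
        from colloidspot.evaluation import _friedman_ranks

        ranks = _friedman_ranks(mat)
        np.testing.assert_allclose(ranks.sum(axis=0), 6 * 7 / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((5, 12))
        table = cs.friedman_test(mat)
        ref_stat, ref_p = stats.friedmanchisquare(*mat)
        assert table.statistic == pytest.approx(float(ref_stat), abs=1e-9)
        assert table.pvalue == pytest.approx(float(ref_p), abs=1e-9)

    def test_higher_scores_get_better_ranks(self):
        mat = np.array([[0.9, 0.8, 0.95], [0.1, 0.2, 0.3]])
        table = cs.friedman_test(mat)
        assert table.mean_ranks["method_0"] < table.mean_ranks["method_1"]

    def test_pairwise_table_size(self):
        mat = np.random.default_rng(0).random((8, 25))
        table = cs.friedman_test(mat)
        assert len(table.pairwise) == 8 * 7 // 2  # 28 Holm rows for 8 methods

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            cs.friedman_test(np.ones((1, 5)))
        with pytest.raises(ValueError):
            cs.friedman_test(np.ones((3, 1)))


class TestHolm:
    def test_single_p_unchanged(self):
        adj, rej = cs.holm_adjust([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_two_p_step_down_by_hand(self):
        adj, rej = cs.holm_adjust([0.01, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [0.02, 0.04])
        assert rej.all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        p = np.random.default_rng(seed).random(10)
        adj, rej = cs.holm_adjust(p, alpha=0.05)
        ref_rej, ref_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, ref_rej)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotone_and_dominates_raw(self, pvals):
        adj, _ = cs.holm_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.holm_adjust([0.5, 1.2])
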