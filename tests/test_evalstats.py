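"""RMSE, ROC/PPV contracts, Wilcoxon exactness, baseline behaviour."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ddgscan.evalstats import (
    BenchmarkRecord,
    pearson_correlation,
    ppv_curve,
    rmse,
    roc_auc,
    roc_curve,
    single_structure_baseline,
    wilcoxon_squared_errors,
)


def brute_force_signed_rank_p(diffs: np.ndarray) -> float:
    """Exhaustive 2^n oracle: mid-ranked |d|, every sign assignment
    equally likely, two-sided tail on |W+ - S/2|."""
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - total / 2)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2) >= dev - 1e-9:
            count += 1
    return count / 2**n


class TestRmse:
    def test_identical_vectors_zero(self):
        assert rmse([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_unit_errors(self):
        assert rmse([1.0, -1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_three_four_errors(self):
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(math.sqrt(25 / 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestRoc:
    def test_two_point_enumeration(self):
        # pred = exp = {-1, +1}: at the midpoint threshold 0 the negative
        # mutation is a test positive and a gold positive
        points = roc_curve([-1.0, 1.0], [-1.0, 1.0])
        mid = next(p for p in points if p.threshold == 0.0)
        assert (mid.tp, mid.fp, mid.tn, mid.fn) == (1, 0, 1, 0)
        assert mid.tpr == 1.0 and mid.tnr == 1.0

    def test_endpoints_present(self):
        points = roc_curve([-1.0, 0.5, 1.0], [-1.0, 1.0, 1.0])
        assert points[0].tpr == 1.0 and points[0].tnr == 0.0  # +inf: all positive
        assert points[-1].tpr == 0.0 and points[-1].tnr == 1.0  # -inf: none

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(0, 1, 50)
        exp = rng.normal(0, 1, 50)
        for p in roc_curve(pred, exp):
            assert p.tp + p.fp + p.tn + p.fn == 50

    def test_tpr_monotone_as_threshold_tightens(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(0, 1, 200)
        exp = pred + rng.normal(0, 1, 200)
        points = roc_curve(pred, exp)  # swept from +inf down
        tprs = [p.tpr for p in points]
        assert all(a >= b - 1e-12 for a, b in zip(tprs, tprs[1:]))

    def test_perfect_separation_gives_auc_one(self):
        exp = np.array([-2.0, -1.0, 1.0, 2.0])
        assert roc_auc(exp.copy(), exp) == pytest.approx(1.0)

    def test_label_independent_predictions_give_half(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(0, 1, 10_000)
        exp = rng.normal(0, 1, 10_000)
        assert roc_auc(pred, exp) == pytest.approx(0.5, abs=0.02)

    def test_auc_in_unit_interval_and_one_class_rejected(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pred = rng.normal(0, 1, 30)
            exp = rng.normal(0, 1, 30)
            assert 0.0 <= roc_auc(pred, exp) <= 1.0
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_auc([1.0, 2.0], [1.0, 2.0])  # no gold positives


class TestPpv:
    def test_all_test_positives_true_in_separating_range(self):
        exp = [-1.0, -2.0, 1.0, 2.0]
        pred = [-1.0, -2.0, 1.0, 2.0]
        for threshold, ppv, denom in ppv_curve(pred, exp):
            if denom and threshold <= 0:
                assert ppv == 1.0

    def test_half_and_half(self):
        # threshold 0: one TP (exp<0) and one FP (exp>=0)
        curve = ppv_curve([-1.0, -1.0, 1.0, 1.0], [-1.0, 1.0, -1.0, 1.0])
        point = next(c for c in curve if c[0] == 0.0)
        assert point[1] == pytest.approx(0.5)
        assert point[2] == 2

    def test_undefined_when_no_test_positives(self):
        curve = ppv_curve([1.0, 2.0], [-1.0, 1.0])
        strictest = curve[-1]  # threshold -inf
        assert strictest[2] == 0
        assert strictest[1] is None  # undefined, never 0


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        e = [0.5, -1.0, 2.0, 0.3, -0.7]
        assert wilcoxon_squared_errors(e, e) == 1.0

    def test_hand_constructed_n6_matches_enumeration(self):
        single = np.array([2.0, -1.5, 1.2, 0.8, -2.2, 1.9])
        multi = np.array([1.0, -0.5, 0.6, 0.9, -1.0, 0.4])
        p = wilcoxon_squared_errors(single, multi)
        assert p == pytest.approx(
            brute_force_signed_rank_p(single**2 - multi**2), abs=1e-12
        )

    def test_matches_enumeration_on_100_seeded_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 11))
            single = rng.normal(0, 1.5, n)
            multi = rng.normal(0, 1.0, n)
            p = wilcoxon_squared_errors(single, multi)
            oracle = brute_force_signed_rank_p(single**2 - multi**2)
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_strongly_one_sided_differences_significant(self):
        rng = np.random.default_rng(12)
        multi = rng.normal(0, 0.5, 20)
        single = multi + rng.uniform(2.0, 3.0, 20) * np.sign(multi + 1e-9)
        # |single errors| uniformly larger -> all squared differences positive
        p = wilcoxon_squared_errors(single, multi)
        assert p < 0.01

    def test_matches_scipy_on_tie_free_large_n(self):
        rng = np.random.default_rng(13)
        single = rng.normal(0, 1.5, 60)
        multi = rng.normal(0, 1.0, 60)
        ours = wilcoxon_squared_errors(single, multi)
        ref = stats.wilcoxon(
            single**2, multi**2, correction=True, method="approx"
        ).pvalue
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_squared_errors([1.0] * 4, [0.5] * 4)


class TestBaseline:
    def _records(self, rng, n_mutants=200, n_structures=4, sigma=1.5):
        truth = rng.normal(0, 1.5, n_mutants)
        return [
            BenchmarkRecord(
                mutant_id=f"m{i}",
                ddg_experimental=float(truth[i]),
                per_structure_predictions=tuple(
                    truth[i] + rng.normal(0, sigma) for _ in range(n_structures)
                ),
            )
            for i in range(n_mutants)
        ]

    def test_single_structure_records_are_deterministic(self):
        rng = np.random.default_rng(20)
        recs = self._records(rng, n_structures=1)
        base = single_structure_baseline(recs, seed=1)
        exp = [r.ddg_experimental for r in recs]
        pred = [r.per_structure_predictions[0] for r in recs]
        assert base.rmse == pytest.approx(rmse(pred, exp))
        assert base.correlation == pytest.approx(pearson_correlation(pred, exp)[0])

    def test_seed_reproducible(self):
        rng = np.random.default_rng(21)
        recs = self._records(rng)
        a = single_structure_baseline(recs, seed=7)
        b = single_structure_baseline(recs, seed=7)
        assert a.per_randomization_rmse == b.per_randomization_rmse

    def test_averaging_beats_single_structure_in_expectation(self):
        rng = np.random.default_rng(22)
        recs = self._records(rng, n_mutants=2000)
        exp = [r.ddg_experimental for r in recs]
        multi = [r.ddg_predicted_multi for r in recs]
        base = single_structure_baseline(recs, seed=3)
        assert rmse(multi, exp) < base.rmse


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        r_direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson_correlation(x, y)[0] == pytest.approx(r_direct)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
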