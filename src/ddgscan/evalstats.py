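"""Evaluation battery for ddG predictors.

Conventions
-----------
Gold-standard positive: an experimentally affinity-improving mutation,
ddG_experimental strictly < 0 (exact zeros are negatives).  Test positive
at a threshold t: ddG_predicted strictly < t.  The ROC sweeps t from +inf
(everything positive) to -inf (nothing positive) and is reported as TPR
versus TNR; its AUC equals the conventional TPR-vs-FPR area.

PPV = TP / (TP + FP) is *undefined*, not zero, at thresholds where no test
positives exist — at strict thresholds the denominator gets small and a
defined-by-fiat zero would be misleading.

The paired comparison of two predictors uses the Wilcoxon signed-rank test
on their squared errors per mutant: exact tail probabilities (rank-sum
enumeration via dynamic programming, mid-ranks for ties, zero differences
dropped) for n <= 25, normal approximation with continuity correction and
tie-corrected variance above.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BenchmarkRecord",
    "RocPoint",
    "BaselineResult",
    "rmse",
    "roc_curve",
    "roc_auc",
    "ppv_curve",
    "wilcoxon_squared_errors",
    "single_structure_baseline",
    "pearson_correlation",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One mutant: experimental ddG plus per-structure predictions."""

    mutant_id: str
    ddg_experimental: float
    per_structure_predictions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.per_structure_predictions:
            raise ValueError(f"{self.mutant_id}: needs at least one prediction")

    @property
    def n_structures(self) -> int:
        return len(self.per_structure_predictions)

    @property
    def ddg_predicted_multi(self) -> float:
        """Ensemble mean over all available structures."""
        return float(np.mean(self.per_structure_predictions))


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv(self) -> Optional[float]:
        """TP/(TP+FP); None (undefined) when there are no test positives."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Root mean square error between predictions and experiment."""
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.shape != e.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and exp must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((p - e) ** 2)))


def _thresholds(pred: np.ndarray) -> list[float]:
    """Midpoints between consecutive unique predictions, with +/-inf
    sentinels, swept loosest (+inf) to strictest (-inf)."""
    uniq = np.unique(pred)
    mids = [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])]
    return [float("inf"), *reversed(mids), float("-inf")]


def roc_curve(pred: Sequence[float], exp: Sequence[float]) -> list[RocPoint]:
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.shape != e.shape or p.size == 0:
        raise ValueError("pred and exp must be equal-length non-empty vectors")
    gold_pos = e < 0
    points = []
    for t in _thresholds(p):
        test_pos = p < t
        tp = int(np.sum(test_pos & gold_pos))
        fp = int(np.sum(test_pos & ~gold_pos))
        fn = int(np.sum(~test_pos & gold_pos))
        tn = int(np.sum(~test_pos & ~gold_pos))
        points.append(RocPoint(threshold=t, tp=tp, fp=fp, tn=tn, fn=fn))
    return points


def roc_auc(pred: Sequence[float], exp: Sequence[float]) -> float:
    """Area under the ROC; equals the usual TPR-vs-FPR area."""
    e = np.asarray(exp, dtype=float)
    if not ((e < 0).any() and (e >= 0).any()):
        raise ValueError("AUC undefined: need both gold positives and negatives")
    points = roc_curve(pred, exp)
    tnr = np.array([pt.tnr for pt in points])
    tpr = np.array([pt.tpr for pt in points])
    order = np.argsort(tnr, kind="stable")
    return float(np.trapezoid(tpr[order], tnr[order]))


def ppv_curve(
    pred: Sequence[float], exp: Sequence[float]
) -> list[tuple[float, Optional[float], int]]:
    """(threshold, PPV or None, TP+FP) per threshold; the denominator is
    reported alongside because PPV grows erratic as it shrinks."""
    return [(pt.threshold, pt.ppv, pt.tp + pt.fp) for pt in roc_curve(pred, exp)]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank on squared errors
# ---------------------------------------------------------------------------


def _signed_rank_p_exact(ranks: np.ndarray, signs: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of the rank-sum distribution.

    p = P(|W+ - S/2| >= |w_obs - S/2|) under random independent signs,
    where S is the total rank sum.  Mid-ranks are handled by doubling to
    integers; the distribution is built by dynamic programming, equivalent
    to (but far cheaper than) enumerating all 2^n sign assignments.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w_obs = float(np.sum(2 * ranks[signs > 0]))
    center = total / 2.0
    dev = abs(w_obs - center)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - center) >= dev - 1e-9].sum())


def wilcoxon_squared_errors(
    errors_single: Sequence[float], errors_multi: Sequence[float]
) -> float:
    """Two-sided signed-rank p for paired squared prediction errors.

    Inputs are per-mutant prediction errors (predicted minus experimental)
    of the two predictors; the test compares their squares.  Zero
    differences are dropped; tied absolute differences get mid-ranks.
    Exact for n <= 25 remaining pairs, normal approximation with continuity
    correction above.  All-zero differences give p = 1.
    """
    a = np.asarray(errors_single, dtype=float) ** 2
    b = np.asarray(errors_multi, dtype=float) ** 2
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired observations")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    signs = np.sign(d)
    if n <= 25:
        return min(1.0, _signed_rank_p_exact(ranks, signs))
    w_plus = float(ranks[signs > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on mid-ranks
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Baseline and correlation
# ---------------------------------------------------------------------------


@dataclass
class BaselineResult:
    rmse: float  # averaged over randomizations
    correlation: float
    per_randomization_rmse: list[float]
    per_randomization_correlation: list[float]


def single_structure_baseline(
    records: Sequence[BenchmarkRecord],
    n_randomizations: int = 5,
    seed: int = 0,
) -> BaselineResult:
    """Single-structure reference: pick one structure per mutant at random,
    compute RMSE and correlation, repeat, and average over randomizations.

    Mutants with exactly one structure always contribute that structure,
    so with all-single records the baseline is deterministic.
    """
    if not records:
        raise ValueError("no benchmark records")
    rng = np.random.default_rng(seed)
    exp = np.array([r.ddg_experimental for r in records])
    rmses, corrs = [], []
    for _ in range(n_randomizations):
        picks = np.array(
            [
                r.per_structure_predictions[rng.integers(r.n_structures)]
                for r in records
            ]
        )
        rmses.append(rmse(picks, exp))
        corrs.append(pearson_correlation(picks, exp)[0])
    return BaselineResult(
        rmse=float(np.mean(rmses)),
        correlation=float(np.mean(corrs)),
        per_randomization_rmse=rmses,
        per_randomization_correlation=corrs,
    )


def pearson_correlation(
    pred: Sequence[float], exp: Sequence[float]
) -> tuple[float, float]:
    """Product-moment r and its two-sided p (t-distribution transform)."""
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.shape != e.shape or p.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(p) == 0 or np.std(e) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, pval = stats.pearsonr(p, e)
    return float(r), float(pval)
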