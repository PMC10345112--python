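"""Spike-in benchmarking and performance metrics.

The spike-in harness inserts a scored pathogenic variant into a control
sample's candidate list and records the rank it achieves; aggregating over
variants x samples gives a solve curve (cumulative fraction of cases solved
within the top k ranks) and its normalized area, where 1 means every case
solved on the first guess and 0 means none solved within 20 guesses.

Classification metrics (precision/recall/F1, one-vs-rest ROC and PR areas),
probability calibration and a bootstrap Mann-Whitney comparison of two
score sets complete the harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress, mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from .prioritization import (
    UNRANKED,
    CandidateMode,
    CandidateScore,
    rank_of,
)


@dataclass(frozen=True)
class SpikeInCase:
    sample_id: str
    spiked_variant_id: str
    spiked_zygosity: str  # "het-as-dominant" | "hom-as-recessive"
    achieved_rank: int    # 1-based; UNRANKED (0) when never ranked

    def __post_init__(self):
        if self.achieved_rank < 0:
            raise ValueError("rank must be >= 1, or UNRANKED (0)")


@dataclass(frozen=True)
class SolveCurve:
    k: np.ndarray               # 1..kmax
    solved_fraction: np.ndarray  # non-decreasing, in [0, 1]

    def __post_init__(self):
        if np.any(np.diff(self.solved_fraction) < 0):
            raise ValueError("solve curve must be non-decreasing")


def spike_in(control_candidates: Sequence[CandidateScore],
             sample_id: str, variant_id: str, score: float,
             variant_class: str) -> SpikeInCase:
    """Rank a spiked-in variant among a control sample's final scores.

    Dominant variants enter as heterozygous dominant candidates ranked by
    their dominant score; recessive variants enter as homozygotes ranked by
    their recessive score (a same-score compound-het pair would rank
    identically, since the harmonic mean of equal scores is that score).
    """
    if variant_class == "dominant":
        mode, zyg = CandidateMode.DOMINANT_HET, "het-as-dominant"
    elif variant_class == "recessive":
        mode, zyg = CandidateMode.RECESSIVE_HOM, "hom-as-recessive"
    else:
        raise ValueError(f"variant_class must be dominant|recessive, got {variant_class!r}")
    spiked = CandidateScore((variant_id,), f"__spiked__{variant_id}", mode, score)
    pool = list(control_candidates) + [spiked]
    achieved = rank_of(pool, [variant_id])
    return SpikeInCase(sample_id, variant_id, zyg, achieved)


def solve_curve(cases: Sequence[SpikeInCase], kmax: int = 20) -> SolveCurve:
    """Cumulative proportion of cases whose causal variant ranks <= k."""
    if not cases:
        raise ValueError("no spike-in cases")
    ranks = np.array([c.achieved_rank for c in cases])
    ranks = np.where(ranks == UNRANKED, kmax + 10**9, ranks)
    k = np.arange(1, kmax + 1)
    frac = (ranks[None, :] <= k[:, None]).mean(axis=1)
    return SolveCurve(k, frac)


def topk_auc(curve: SolveCurve) -> float:
    """Normalized trapezoidal area of the solve curve over x=(k-1)/(kmax-1).

    1.0 iff every case is solved on the first guess; 0.0 iff none are solved
    within kmax guesses.
    """
    kmax = curve.k.shape[0]
    if kmax < 2:
        raise ValueError("need kmax >= 2")
    x = (curve.k - 1) / (kmax - 1)
    return float(np.trapezoid(curve.solved_fraction, x))


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision TP/(FP+TP), recall TP/(FN+TP), F1 = TP/(TP + (FP+FN)/2).

    All-zero denominators yield 0 with a warning rather than an error.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning 0")
            return 0.0
        return num / den

    precision = safe(tp, fp + tp, "precision")
    recall = safe(tp, fn + tp, "recall")
    f1 = safe(tp, tp + 0.5 * (fp + fn), "F1")
    return precision, recall, f1


def pr_roc_curves(scores: np.ndarray, labels: np.ndarray
                  ) -> dict[int, dict[str, float]]:
    """One-vs-rest auROC and auPRC per class.

    ``scores`` is (N, C) class probabilities, ``labels`` integer classes.
    Raises on single-class label vectors, where neither area is defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes present in labels")
    out: dict[int, dict[str, float]] = {}
    for c in range(scores.shape[1]):
        y = (labels == c).astype(int)
        if y.min() == y.max():
            continue  # this class absent or universal; area undefined
        out[c] = {
            "auroc": float(roc_auc_score(y, scores[:, c])),
            "auprc": float(average_precision_score(y, scores[:, c])),
        }
    return out


def macro_auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean one-vs-rest auPRC across the classes present in ``labels``."""
    per_class = pr_roc_curves(scores, labels)
    return float(np.mean([d["auprc"] for d in per_class.values()]))


def calibration(preds: np.ndarray, labels: np.ndarray,
                n_bins: int = 10) -> dict[int, dict[str, float]]:
    """Reliability of class probabilities: slope and r^2 of empirical class
    frequency regressed on binned predicted confidence, per class.

    A well-calibrated model has slope ~ 1; constant over-confident
    predictions regress to slope ~ 0.  Empty bins are skipped with a
    warning.
    """
    if n_bins < 3:
        raise ValueError("need n_bins >= 3")
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out: dict[int, dict[str, float]] = {}
    for c in range(preds.shape[1]):
        conf = preds[:, c]
        hit = (labels == c).astype(float)
        xs, ys = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (conf >= lo) & (conf < hi if hi < 1.0 else conf <= hi)
            if not in_bin.any():
                warnings.warn(f"class {c}: empty calibration bin [{lo:.2f}, {hi:.2f})")
                continue
            xs.append(conf[in_bin].mean())
            ys.append(hit[in_bin].mean())
        if len(xs) < 2:
            continue
        fit = linregress(xs, ys)
        out[c] = {"slope": float(fit.slope), "r_squared": float(fit.rvalue ** 2)}
    return out


def bootstrap_compare(scores_a: np.ndarray, scores_b: np.ndarray,
                      labels: np.ndarray, n_iter: int = 1000,
                      seed: int = 0) -> float:
    """One-sided p-value that method A's auPRC exceeds method B's.

    Bootstrap-resamples the evaluation set ``n_iter`` times, computes each
    method's auPRC per resample, then applies a one-sided Mann-Whitney U
    test (A > B) to the two auPRC samples.
    """
    if n_iter < 10:
        raise ValueError("need n_iter >= 10")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape[0] != labels.shape[0] or scores_b.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must share a label vector")
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    auprc_a, auprc_b = [], []
    for _ in range(n_iter):
        idx = rng.integers(0, n, size=n)
        y = labels[idx]
        if y.min() == y.max():
            continue
        auprc_a.append(average_precision_score(y, scores_a[idx]))
        auprc_b.append(average_precision_score(y, scores_b[idx]))
    stat = mannwhitneyu(auprc_a, auprc_b, alternative="greater",
                        method="asymptotic")
    return float(stat.pvalue)
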