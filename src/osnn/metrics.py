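"""Ordinal prediction and variable-selection evaluation.

Prediction: accuracy, macro-averaged one-vs-rest AUC (Mann-Whitney, ties count
0.5), and the Ranked Probability Score, the mean squared discrepancy between
predicted and observed cumulative class distributions — the natural proper score
for ordinal predictions.  Selection: true/false positive rates against a known
ground truth, and the observed occurrence index (OOI), the selection frequency
of each variable across repeated data splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PredictionMetrics",
    "SelectionMetrics",
    "accuracy",
    "macro_auc",
    "rps",
    "prediction_metrics",
    "selection_rates",
    "ooi",
]


@dataclass(frozen=True)
class PredictionMetrics:
    macro_auc: float
    rps: float
    accuracy: float


@dataclass(frozen=True)
class SelectionMetrics:
    tpr_main: float
    fpr_main: float
    tpr_inter: float
    fpr_inter: float


def accuracy(labels_pred: np.ndarray, y: np.ndarray) -> float:
    """Fraction of exact label matches."""
    labels_pred = np.asarray(labels_pred)
    y = np.asarray(y)
    if labels_pred.shape != y.shape:
        raise ValueError("prediction and truth must have equal length")
    return float(np.mean(labels_pred == y))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUC via the rank-sum (Mann-Whitney) statistic; ties -> 0.5."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    ranks = rankdata(scores)  # average ranks implement the tie convention
    auc = (ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def macro_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """Unweighted mean of one-vs-rest AUCs over the classes present in ``y``.

    Class k uses probs[:, k-1] as the score.  Classes absent from ``y`` (or
    without negatives) cannot be scored; they are skipped with a warning and the
    remaining classes are averaged.  Fewer than two distinct labels makes the
    metric undefined.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("macro-AUC undefined with fewer than 2 distinct labels")
    K = probs.shape[1]
    aucs = []
    skipped = []
    for k in range(1, K + 1):
        positive = y == k
        if positive.sum() == 0 or positive.sum() == len(y):
            skipped.append(k)
            continue
        aucs.append(_binary_auc(probs[:, k - 1], positive))
    if skipped:
        warnings.warn(
            f"macro-AUC: classes {skipped} have no positives or no negatives; "
            "averaging the remaining classes",
            stacklevel=2,
        )
    return float(np.mean(aucs))


def rps(probs: np.ndarray, y: np.ndarray, normalized: bool = False) -> float:
    """Ranked Probability Score: mean_i sum_{k<K} (F_hat_ik - 1{y_i <= k})^2.

    F_hat_ik is the predicted cumulative probability of classes 1..k.  Zero iff
    every prediction puts all mass on the true class.  ``normalized=True``
    divides the per-sample sum by K-1.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    K = probs.shape[1]
    cum_pred = np.cumsum(probs, axis=1)[:, : K - 1]          # (n, K-1)
    ks = np.arange(1, K)
    cum_obs = (y[:, None] <= ks[None, :]).astype(float)
    per_sample = ((cum_pred - cum_obs) ** 2).sum(axis=1)
    if normalized:
        per_sample = per_sample / (K - 1)
    return float(per_sample.mean())


def prediction_metrics(probs: np.ndarray, y: np.ndarray) -> PredictionMetrics:
    labels = 1 + np.argmax(probs, axis=1)
    return PredictionMetrics(
        macro_auc=macro_auc(probs, y),
        rps=rps(probs, y),
        accuracy=accuracy(labels, y),
    )


def selection_rates(sel, truth, p: int, q: int) -> SelectionMetrics:
    """TPR/FPR of selected main effects and interactions against the truth.

    ``sel`` needs ``main_selected`` / ``inter_selected`` sets; ``truth`` needs
    ``important_main`` / ``important_inter``.  FPR denominators are the null-set
    sizes p - |truth_main| and p*q - |truth_inter|.
    """
    truth_main = set(int(j) for j in truth.important_main)
    truth_inter = set((int(j), int(d)) for j, d in truth.important_inter)
    if not truth_main or not truth_inter:
        raise ValueError("TPR undefined for an empty truth set")
    sel_main = set(sel.main_selected)
    sel_inter = set(sel.inter_selected)
    tpr_main = len(sel_main & truth_main) / len(truth_main)
    fpr_main = len(sel_main - truth_main) / (p - len(truth_main))
    tpr_inter = len(sel_inter & truth_inter) / len(truth_inter)
    fpr_inter = len(sel_inter - truth_inter) / (p * q - len(truth_inter))
    return SelectionMetrics(tpr_main, fpr_main, tpr_inter, fpr_inter)


def ooi(selections: Iterable, universe: Iterable) -> Mapping:
    """Observed occurrence index: per-variable selection frequency across splits.

    ``universe`` lists the variables to report (e.g. range(p) for main effects,
    or (j, d) pairs for interactions); each selection contributes its
    ``main_selected`` and ``inter_selected`` members.
    """
    selections = list(selections)
    if not selections:
        raise ValueError("ooi requires at least one selection")
    n = len(selections)
    counts: dict = {v: 0 for v in universe}
    for sel in selections:
        chosen = set(sel.main_selected) | set(sel.inter_selected)
        for v in counts:
            if v in chosen:
                counts[v] += 1
    return {v: c / n for v, c in counts.items()}
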