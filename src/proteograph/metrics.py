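"""Evaluation metrics: AUROC, threshold confusion metrics, risk-bin odds
ratios, and model-driven protein importance."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import softmax_weights


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: probability a random positive outranks a random
    negative, ties credited 0.5.  Computed via the rank-sum identity."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy at a threshold.

    Predicted positive iff score >= threshold.  A ratio with zero denominator
    is reported as NaN (missing), never as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not labels.any() or labels.all():
        raise ValueError("confusion metrics need both classes present")
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / labels.size,
    }


def risk_bin_odds_ratios(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Odds ratios of decile risk bins against the lowest occupied bin.

    Bins are equal-width: [0, 0.1), ..., [0.8, 0.9), [0.9, 1.0].  When any
    cell of a 2x2 comparison is zero, the Haldane-Anscombe 0.5 correction is
    added to all four cells of that comparison.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    bins = np.minimum((scores * 10).astype(int), 9)
    pos = np.bincount(bins[labels == 1], minlength=10)
    neg = np.bincount(bins[labels == 0], minlength=10)
    occupied = np.flatnonzero(pos + neg > 0)
    if occupied.size < 2:
        raise ValueError("need at least two occupied risk bins")
    ref = int(occupied[0])
    rows = []
    for b in range(10):
        if pos[b] + neg[b] == 0:
            odds, logodds = float("nan"), float("nan")
        elif b == ref:
            odds, logodds = 1.0, 0.0
        else:
            a, c = float(pos[b]), float(neg[b])
            d, e = float(pos[ref]), float(neg[ref])
            if min(a, c, d, e) == 0:
                a, c, d, e = a + 0.5, c + 0.5, d + 0.5, e + 0.5
            odds = (a / c) / (d / e)
            logodds = float(np.log10(odds))
        rows.append({
            "bin_low": b / 10, "bin_high": (b + 1) / 10,
            "positives": int(pos[b]), "negatives": int(neg[b]),
            "odds_ratio": odds, "log10_or": logodds,
            "is_reference": b == ref,
        })
    return pd.DataFrame(rows)


def cluster_importance(params, clusters, protein_ids=None) -> list[pd.DataFrame]:
    """Per-cluster softmax importances with protein IDs, sorted descending.

    ``params`` may be a fitted :class:`ModelParameters` or any object with a
    ``lambdas`` attribute; weights in each frame sum to 1.
    """
    lambdas = params.lambdas if hasattr(params, "lambdas") else params
    frames = []
    for k, (members, lam) in enumerate(zip(clusters, lambdas)):
        w = softmax_weights(np.asarray(lam, dtype=float))
        ids = (
            [protein_ids[i] for i in members]
            if protein_ids is not None
            else [str(i) for i in members]
        )
        df = pd.DataFrame({"cluster": k, "protein": ids, "index": list(members), "weight": w})
        frames.append(df.sort_values("weight", ascending=False, kind="stable").reset_index(drop=True))
    return frames
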