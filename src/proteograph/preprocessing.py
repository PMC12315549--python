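"""Expression QC and normalization, plus a simplified differential-expression
biomarker selector.

The chain mirrors a standard Olink-style workflow: drop proteins with more
than 10% missing calls, impute the rest with a k-nearest-neighbor rule over
co-expressed protein rows, run differential expression on the (log-scale)
imputed values, and only then squash each protein row through z-score +
logistic scaling into (0, 1).

The differential-expression stage is a deliberately simple stand-in for
moderated-t pipelines: an unmoderated Welch two-sample t per protein per
subtype with Benjamini-Hochberg adjustment within subtype.  Without variance
moderation it is slightly conservative for small groups; selected unions can
differ from an empirical-Bayes analysis near the significance boundary.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, RawExpressionMatrix, SubtypeLabels

logger = logging.getLogger(__name__)


def filter_missing(raw: RawExpressionMatrix, max_rate: float = 0.10) -> RawExpressionMatrix:
    """Drop proteins whose missing fraction strictly exceeds ``max_rate``."""
    rates = raw.missing_mask.mean(axis=1)
    keep = rates <= max_rate
    dropped = [pid for pid, k in zip(raw.protein_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d proteins over the missing-rate cutoff: %s",
                    len(dropped), ", ".join(dropped))
    if not keep.any():
        raise ValueError("all proteins exceed the missing-rate cutoff")
    return RawExpressionMatrix(
        raw.values[keep], [p for p, k in zip(raw.protein_ids, keep) if k], raw.sample_ids
    )


def knn_impute(raw: RawExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """Replace each missing cell with the mean of that sample's values over
    the k nearest protein rows.

    Distance between protein rows is the plain Euclidean norm over their
    co-observed entries; rows with no co-observed entries are unreachable.
    Only proteins observed at the target sample are candidate neighbors.
    """
    V = raw.values.copy()
    miss = np.isnan(V)
    all_missing = np.flatnonzero(miss.all(axis=1))
    if all_missing.size:
        raise ValueError(f"protein {raw.protein_ids[all_missing[0]]} has no observed values")
    if not miss.any():
        return ExpressionMatrix(V, raw.protein_ids, raw.sample_ids)
    p = V.shape[0]
    # pairwise Euclidean over co-observed entries
    dist = np.full((p, p), np.inf)
    for i in range(p):
        for j in range(i + 1, p):
            co = ~miss[i] & ~miss[j]
            if co.any():
                d = float(np.sqrt(np.sum((V[i, co] - V[j, co]) ** 2)))
                dist[i, j] = dist[j, i] = d
    out = V.copy()
    for i in range(p):
        cells = np.flatnonzero(miss[i])
        if not cells.size:
            continue
        order = np.argsort(dist[i], kind="stable")
        for j in cells:
            neighbors = [r for r in order if r != i and not miss[r, j] and np.isfinite(dist[i, r])]
            if len(neighbors) < k:
                raise ValueError(
                    f"protein {raw.protein_ids[i]} has only {len(neighbors)} usable "
                    f"neighbors at sample {raw.sample_ids[j]} (need k={k})"
                )
            out[i, j] = V[neighbors[:k], j].mean()
    return ExpressionMatrix(out, raw.protein_ids, raw.sample_ids)


def scale_expression(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-protein z-score (sample SD, n-1 denominator) followed by the
    logistic function, mapping every row into (0, 1)."""
    if x.scaled:
        raise ValueError("expression matrix is already scaled; scaling twice would distort it")
    V = x.values
    sd = V.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"protein {x.protein_ids[flat[0]]} has zero variance; cannot z-score")
    Z = (V - V.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(expit(Z), x.protein_ids, x.sample_ids, scaled=True)


def differential_expression(x: ExpressionMatrix, y: SubtypeLabels) -> pd.DataFrame:
    """Welch two-sample t per protein per subtype, with BH adjustment within
    subtype.  ``log2fc`` is mean(positive) - mean(negative), i.e. a log2
    fold-change when the input is on a log2-like (NPX) scale."""
    if x.n_samples != y.values.shape[1]:
        raise ValueError("expression and labels cover different sample counts")
    frames = []
    for s, name in enumerate(y.subtype_names):
        mask = y.values[s].astype(bool)
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"subtype {name} needs >= 2 samples in each group")
        pos, neg = x.values[:, mask], x.values[:, ~mask]
        t, pval = ttest_ind(pos, neg, axis=1, equal_var=False)
        _, padj, _, _ = multipletests(pval, method="fdr_bh")
        log2fc = pos.mean(axis=1) - neg.mean(axis=1)
        frames.append(pd.DataFrame({
            "protein": x.protein_ids,
            "subtype": name,
            "log2fc": log2fc,
            "t": t,
            "p": pval,
            "p_adj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }))
    return pd.concat(frames, ignore_index=True)


def union_biomarkers(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Union over subtypes of proteins with BH-adjusted p below ``alpha``,
    in stable first-appearance order."""
    hits = table.loc[table["p_adj"] < alpha, "protein"]
    seen: dict[str, None] = {}
    for pid in hits:
        seen.setdefault(pid, None)
    if not seen:
        raise ValueError(
            f"no protein passes adjusted p < {alpha}; consider relaxing the threshold"
        )
    return list(seen)
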