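"""Repeated k-fold protocol: train on discovery folds, score a fixed
validation cohort.

Each of ``n_repeats x n_folds`` fits uses the 4/5 training portion of the
discovery set and predicts the held-out validation cohort, so the protocol
yields ``n_repeats * n_folds`` prediction vectors per subtype (100 with the
default 20 x 5).  Folds are stratified on the joint label combination when
every combination has at least ``n_folds`` members, otherwise on the rarest
single subtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SUBTYPES
from .estimator import PropagationClassifier, TrainingConfig
from .metrics import auroc, confusion_metrics

_MAX_FOLD_ATTEMPTS = 50


def _stratify_key(Y: np.ndarray, n_folds: int) -> np.ndarray:
    """Joint-combination key if feasible, else the rarest single subtype."""
    joint = np.array([int("".join(map(str, row)), 2) for row in Y])
    _, counts = np.unique(joint, return_counts=True)
    if counts.min() >= n_folds:
        return joint
    prevalence = Y.mean(axis=0)
    rarest = int(np.argmin(np.where(prevalence > 0.5, 1 - prevalence, prevalence)))
    return Y[:, rarest]


def make_folds(Y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified fold assignment; returns a list of index arrays."""
    n = Y.shape[0]
    key = _stratify_key(Y, n_folds)
    fold_of = np.empty(n, dtype=int)
    for value in np.unique(key):
        idx = np.flatnonzero(key == value)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def _folds_trainable(Y: np.ndarray, folds: list[np.ndarray]) -> bool:
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(Y.shape[0]), test_idx)
        pos = Y[train].sum(axis=0)
        if np.any(pos == 0) or np.any(pos == train.size):
            return False
    return True


@dataclass
class CVResult:
    """Ensemble of repeated predictions on the fixed validation cohort."""

    predictions: np.ndarray  # (n_repeats * n_folds, n_tasks, n_val)
    metrics: pd.DataFrame  # one row per prediction x subtype
    summary: pd.DataFrame  # mean and 95% CI per subtype x metric
    task_names: list[str]


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean with normal-approximation 95% CI across repeated predictions."""
    rows = []
    value_cols = [c for c in metrics.columns if c not in ("subtype", "repeat", "fold")]
    for subtype, grp in metrics.groupby("subtype", sort=False):
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:  # a ratio undefined in every repeat stays missing
                mean = float("nan")
                half = float("nan")
            else:
                mean = v.mean()
                half = 1.96 * v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            rows.append(
                {"subtype": subtype, "metric": col, "mean": mean,
                 "ci_low": mean - half, "ci_high": mean + half}
            )
    return pd.DataFrame(rows)


def cross_validate(
    x,
    net,
    clusters,
    y,
    test_x,
    test_y,
    config: TrainingConfig | None = None,
    n_repeats: int = 20,
    n_folds: int = 5,
    estimator: PropagationClassifier | None = None,
    threshold: float = 0.5,
) -> CVResult:
    """Run the repeated-CV protocol.

    ``x``/``test_x`` are (n_samples, p) arrays (discovery / fixed validation),
    ``y``/``test_y`` the matching (n_samples, n_tasks) binary labels.  ``net``
    is the (p, p) adjacency and ``clusters`` the protein-index partition; an
    explicit ``estimator`` (e.g. an ablation variant) overrides them.
    """
    config = config or TrainingConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    test_x = np.asarray(test_x, dtype=float)
    test_y = np.asarray(test_y)
    if estimator is None:
        estimator = PropagationClassifier(
            network=net,
            clusters=clusters,
            delta=config.delta,
            learning_rate=config.learning_rate,
            max_iter=config.max_iters,
            tol=config.tol,
            phi_floor=config.phi_floor,
            init_phi=config.init_phi,
        )
    q = y.shape[1]
    names = list(SUBTYPES) if q == 3 else [f"task{s}" for s in range(q)]
    rng = np.random.default_rng(config.seed)

    preds = []
    rows = []
    from sklearn.base import clone

    for rep in range(n_repeats):
        folds = None
        for _ in range(_MAX_FOLD_ATTEMPTS):
            cand = make_folds(y, n_folds, rng)
            if _folds_trainable(y, cand):
                folds = cand
                break
        if folds is None:
            raise RuntimeError(
                f"could not draw {n_folds} folds with both classes per subtype "
                f"in every training split after {_MAX_FOLD_ATTEMPTS} attempts"
            )
        for f, test_idx in enumerate(folds):
            train = np.setdiff1d(np.arange(y.shape[0]), test_idx)
            est = clone(estimator)
            est.fit(x[train], y[train], task_names=names)
            P = est.predict_proba(test_x)  # n_val x q
            preds.append(P.T)
            for s in range(q):
                cm = confusion_metrics(P[:, s], test_y[:, s], threshold=threshold)
                rows.append(
                    {"subtype": names[s], "repeat": rep, "fold": f,
                     "auroc": auroc(P[:, s], test_y[:, s]), **cm}
                )
    metrics = pd.DataFrame(rows)
    return CVResult(
        predictions=np.asarray(preds),
        metrics=metrics,
        summary=summarize_metrics(metrics),
        task_names=names,
    )

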