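"""Forward model: softmax cluster aggregation, logistic risk heads, and the
regularized multi-task objective.

The aggregated effect of cluster ``k`` is the convex combination
``Z_k = sum_{i in C_k} Lambda_k^(i) H^(i)`` with within-cluster softmax weights
``Lambda_k = softmax(lambda_k)``, and each subtype head predicts
``P = logistic(theta' Z)`` with no intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .graph import normalized_laplacian, propagate, propagation_operator

#: probabilities are clipped to [EPS, 1 - EPS] before logs; the cross-entropy
#: is undefined at exactly 0 or 1
EPS = 1e-12


def softmax_weights(lam: np.ndarray) -> np.ndarray:
    """Max-shifted softmax; positive, sums to one, shift-invariant."""
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("lambda vector must be 1-D and nonempty")
    e = np.exp(lam - lam.max())
    return e / e.sum()


def aggregate_clusters(
    H: np.ndarray, clusters: list[list[int]], lambdas: list[np.ndarray]
) -> np.ndarray:
    """Stack the softmax-weighted sums of each cluster's propagated rows."""
    H = np.asarray(H, dtype=float)
    if len(clusters) != len(lambdas):
        raise ValueError(f"{len(clusters)} clusters but {len(lambdas)} lambda vectors")
    Z = np.empty((len(clusters), H.shape[1]))
    for k, (members, lam) in enumerate(zip(clusters, lambdas)):
        members = np.asarray(members, dtype=int)
        if members.size != np.asarray(lam).size:
            raise ValueError(
                f"cluster {k} has {members.size} members but lambda length {np.asarray(lam).size}"
            )
        if members.size and (members.min() < 0 or members.max() >= H.shape[0]):
            raise IndexError(f"cluster {k} indexes outside the protein range")
        Z[k] = softmax_weights(lam) @ H[members]
    return Z


def predict_risk(Z: np.ndarray, thetas: list[np.ndarray]) -> np.ndarray:
    """Per-subtype logistic risks, strictly inside (0, 1)."""
    Z = np.asarray(Z, dtype=float)
    P = np.empty((len(thetas), Z.shape[1]))
    for s, theta in enumerate(thetas):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (Z.shape[0],):
            raise ValueError(
                f"theta for head {s} has shape {theta.shape}, expected ({Z.shape[0]},)"
            )
        P[s] = expit(theta @ Z)
    return np.clip(P, EPS, 1.0 - EPS)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != label shape {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def forward(
    params,
    X: np.ndarray,
    W: np.ndarray | None,
    clusters: list[list[int]] | None,
    L: np.ndarray | None = None,
    factor=None,
):
    """Run propagation, aggregation and prediction; returns ``(H, Z, P)``.

    ``params.phi is None`` skips propagation (``H = X``); ``params.lambdas is
    None`` skips aggregation (``Z = H``).  Intermediates are returned so the
    gradient pass can reuse them.
    """
    X = np.asarray(X, dtype=float)
    if params.phi is not None:
        if L is None:
            L = normalized_laplacian(W)
        if factor is None:
            factor = propagation_operator(L, params.phi)
        H = propagate(X, L, params.phi, factor=factor)
    else:
        H = X
    if params.lambdas is not None:
        Z = aggregate_clusters(H, clusters, params.lambdas)
    else:
        Z = H
    P = predict_risk(Z, params.thetas)
    return H, Z, P


def total_objective(
    params,
    X: np.ndarray,
    W: np.ndarray | None,
    clusters: list[list[int]] | None,
    Y: np.ndarray,
    L: np.ndarray | None = None,
    P: np.ndarray | None = None,
) -> float:
    """Sum of per-subtype cross-entropies plus ``delta`` times the summed
    squared l2 norms of all active parameter blocks."""
    Y = np.asarray(Y)
    if P is None:
        _, _, P = forward(params, X, W, clusters, L=L)
    loss = sum(bce_loss(P[s], Y[s]) for s in range(Y.shape[0]))
    return float(loss + params.delta * params.l2_penalty())
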