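"""Analytic gradients of the regularized multi-task objective.

Every formula here is validated against central finite differences of the full
objective in the test suite; that numerical agreement, not any printed form,
is the binding contract.  Two places where the obvious chain rule is the
implemented form:

* the backprop weight from ``Z_k`` onto a member row of ``H`` is the softmax
  weight ``Lambda_k^(i)``, not the raw ``lambda_k^(i)``;
* with ``A = Phi + L`` and ``S = X - H``, the phi-derivative of the loss is
  ``rowsum((A^{-1} G) * S)`` for upstream gradient ``G = dL/dH`` (``A`` is
  symmetric, and ``dH/dphi_i = A^{-1} E_ii S`` exploits
  ``A^{-1}{I - A^{-1}Phi}X = A^{-1}(X - H)``).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve

from .model import softmax_weights


def dloss_dZ(Z: np.ndarray, P: np.ndarray, Y: np.ndarray, thetas) -> np.ndarray:
    """Cross-entropy gradient w.r.t. the cluster effects:
    ``sum_s (1/n) theta_s (P_s - Y_s)``, an ``m x n`` matrix."""
    n = Z.shape[1]
    G = np.zeros_like(Z)
    for s, theta in enumerate(thetas):
        G += np.outer(np.asarray(theta, dtype=float), P[s] - Y[s]) / n
    return G


def grad_theta(
    Z: np.ndarray, p: np.ndarray, y: np.ndarray, theta: np.ndarray, delta: float
) -> np.ndarray:
    """``(1/n) Z (P - Y)' + 2 delta theta`` for one subtype head."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or Z.shape[1] != p.shape[0]:
        raise ValueError("dimension mismatch between Z, predictions and labels")
    n = p.shape[0]
    return Z @ (p - y) / n + 2.0 * delta * np.asarray(theta, dtype=float)


def grad_lambda(
    dZk: np.ndarray, Hk: np.ndarray, lam_k: np.ndarray, delta: float
) -> np.ndarray:
    """Softmax-Jacobian pullback for one cluster:
    ``(dL/dZ_k) H_k' {Diag(Lam_k) - Lam_k Lam_k'} + 2 delta lambda_k``."""
    dZk = np.asarray(dZk, dtype=float)
    Hk = np.asarray(Hk, dtype=float)
    lam_k = np.asarray(lam_k, dtype=float)
    if Hk.shape != (lam_k.size, dZk.size):
        raise ValueError(
            f"H_k shape {Hk.shape} incompatible with lambda length {lam_k.size} "
            f"and n = {dZk.size}"
        )
    w = softmax_weights(lam_k)
    v = Hk @ dZk  # length p_k
    return w * v - w * (w @ v) + 2.0 * delta * lam_k


def backprop_to_H(
    dZ: np.ndarray, clusters: list[list[int]], lambdas: list[np.ndarray], p: int
) -> np.ndarray:
    """Spread ``dL/dZ`` back onto protein rows: row ``i`` in cluster ``k``
    receives ``Lambda_k^(i) * dL/dZ_k``."""
    dZ = np.asarray(dZ, dtype=float)
    if dZ.shape[0] != len(clusters):
        raise ValueError(f"dL/dZ has {dZ.shape[0]} rows for {len(clusters)} clusters")
    G = np.zeros((p, dZ.shape[1]))
    for k, (members, lam) in enumerate(zip(clusters, lambdas)):
        w = softmax_weights(np.asarray(lam, dtype=float))
        G[np.asarray(members, dtype=int)] = w[:, None] * dZ[k][None, :]
    return G


def grad_phi(
    dH: np.ndarray,
    X: np.ndarray,
    H: np.ndarray,
    phi: np.ndarray,
    factor,
    delta: float,
) -> np.ndarray:
    """Propagation-weight gradient ``rowsum((A^{-1} dH) * (X - H)) + 2 delta phi``
    where ``factor`` is the Cholesky factorization of ``A = Phi + L``."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("phi must be strictly positive")
    dH = np.asarray(dH, dtype=float)
    if dH.shape != X.shape:
        raise ValueError(f"dL/dH shape {dH.shape} != X shape {X.shape}")
    M = cho_solve(factor, dH)
    return np.sum(M * (X - H), axis=1) + 2.0 * delta * phi
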