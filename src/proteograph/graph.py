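"""Normalized Laplacian construction and closed-form network propagation.

Propagation replaces each protein's signal with the optimum of a smoothness /
steadiness trade-off over the PPI network,

    min_H  Tr(H' L H) + Tr((H - X)' Phi (H - X)),

whose unique minimizer is ``H = (Phi + L)^{-1} Phi X``.  ``L`` is positive
semi-definite and ``Phi`` has strictly positive diagonal, so ``Phi + L`` is
symmetric positive definite and is solved by Cholesky factorization; no
explicit inverse is formed.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """``L = I - D^{-1/2} W D^{-1/2}`` for a symmetric nonnegative adjacency.

    Zero-degree nodes get ``0^{-1/2} := 0``, so their Laplacian row equals the
    identity row: an isolated protein receives no smoothing, only the
    Phi-anchoring toward its own signal.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {W.shape}")
    bad = np.argwhere(W < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"negative adjacency entry W[{i},{j}] = {W[i, j]}")
    asym = np.argwhere(~np.isclose(W, W.T, rtol=1e-10, atol=1e-12))
    if asym.size:
        i, j = asym[0]
        raise ValueError(f"adjacency not symmetric at ({i},{j}): {W[i, j]} vs {W[j, i]}")
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, deg**-0.5, 0.0)
    L = -dinv[:, None] * W * dinv[None, :]
    np.fill_diagonal(L, 1.0)
    # exact symmetry despite floating-point products
    return (L + L.T) / 2.0


def _check_phi(phi: np.ndarray, p: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (p,):
        raise ValueError(f"phi must have shape ({p},), got {phi.shape}")
    if np.any(phi <= 0):
        bad = int(np.argmin(phi))
        raise ValueError(f"phi must be strictly positive (phi[{bad}] = {phi[bad]})")
    return phi


def propagation_operator(L: np.ndarray, phi: np.ndarray):
    """Cholesky factorization of ``Phi + L``; reused across the forward solve
    and the phi-gradient within one training iteration."""
    phi = _check_phi(phi, L.shape[0])
    A = L + np.diag(phi)
    return cho_factor(A)


def propagate(
    X: np.ndarray, L: np.ndarray, phi: np.ndarray, factor=None
) -> np.ndarray:
    """Closed-form propagated signals ``H`` solving ``(Phi + L) H = Phi X``."""
    X = np.asarray(X, dtype=float)
    phi = _check_phi(phi, L.shape[0])
    if X.shape[0] != L.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Laplacian is {L.shape[0]}x{L.shape[0]}")
    if factor is None:
        factor = propagation_operator(L, phi)
    return cho_solve(factor, phi[:, None] * X)


def propagation_objective(
    H: np.ndarray, X: np.ndarray, L: np.ndarray, phi: np.ndarray
) -> float:
    """Smoothness + steadiness value ``Tr(H'LH) + Tr((H-X)'Phi(H-X))``."""
    H = np.asarray(H, dtype=float)
    X = np.asarray(X, dtype=float)
    if H.shape != X.shape:
        raise ValueError(f"H shape {H.shape} != X shape {X.shape}")
    if H.shape[0] != L.shape[0]:
        raise ValueError("row count does not match Laplacian size")
    phi = np.asarray(phi, dtype=float)
    smooth = float(np.sum(H * (L @ H)))
    resid = H - X
    steady = float(np.sum(phi[:, None] * resid * resid))
    return smooth + steady
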