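"""Multi-task network-propagation classifier with block gradient descent.

:class:`PropagationClassifier` is a scikit-learn style estimator chaining
closed-form Laplacian propagation, softmax cluster aggregation and one
logistic head per subtype.  Training is block-coordinate gradient descent on
the summed cross-entropy plus an l2 penalty: each iteration updates the
prediction vectors theta (cheapest block), then the per-cluster importances
lambda, then the propagation weights phi (costliest, one new factorization per
trial step), with backtracking halving inside each block so the objective
trace is monotone non-increasing.

Ablation variants are expressed through two constructor switches:

========  ===============  ===========
variant   use_propagation  aggregation
========  ===============  ===========
full      True             "trained"
AM1       True             "uniform"
AM2       True             "none"
AM3       False            "trained"
AM4       False            "none"
========  ===============  ===========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .containers import (
    SUBTYPES,
    ClusterAssignment,
    ExpressionMatrix,
    ModelParameters,
    PPINetwork,
    SubtypeLabels,
)
from .gradients import backprop_to_H, dloss_dZ, grad_lambda, grad_phi, grad_theta
from .graph import normalized_laplacian, propagate, propagation_operator
from .model import EPS, aggregate_clusters, bce_loss

_MAX_HALVINGS = 40


@dataclass
class TrainingConfig:
    """Optimizer settings; the model itself fixes no hyperparameters, so these
    are config-driven with backtracking making the defaults scale-robust."""

    learning_rate: float = 0.5
    max_iters: int = 2000
    tol: float = 1e-7
    delta: float = 1e-3
    phi_floor: float = 1e-4
    init_phi: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.phi_floor <= 0:
            raise ValueError("phi_floor must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be a positive integer")
        if self.tol < 0 or self.delta < 0:
            raise ValueError("tol and delta must be nonnegative")


@dataclass
class FitResult:
    params: ModelParameters
    objective_trace: np.ndarray
    converged: bool
    iterations_run: int


class PropagationClassifier(BaseEstimator):
    """Joint subtype-risk model over a PPI network and functional clusters.

    Parameters
    ----------
    network : (p, p) array
        Symmetric nonnegative adjacency aligned with the feature columns.
        May be ``None`` when ``use_propagation=False``.
    clusters : list of list of int
        Disjoint covering protein-index clusters.  May be ``None`` when
        ``aggregation="none"``.
    delta : float
        l2 regularization coefficient on all trained parameter blocks.
    learning_rate, max_iter, tol, phi_floor, init_phi
        Optimizer settings; see :class:`TrainingConfig`.
    use_propagation : bool
        If False the propagated signal is the raw expression (``H = X``).
    aggregation : {"trained", "uniform", "none"}
        "uniform" freezes the importances at ``1/p_k``; "none" feeds the
        protein-level signals directly to p-dimensional heads.
    """

    def __init__(
        self,
        network=None,
        clusters=None,
        *,
        delta=1e-3,
        learning_rate=0.5,
        max_iter=2000,
        tol=1e-7,
        phi_floor=1e-4,
        init_phi=1.0,
        use_propagation=True,
        aggregation="trained",
    ):
        self.network = network
        self.clusters = clusters
        self.delta = delta
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.phi_floor = phi_floor
        self.init_phi = init_phi
        self.use_propagation = use_propagation
        self.aggregation = aggregation

    # ------------------------------------------------------------------ fit

    def _validate_structure(self, p):
        if self.aggregation not in ("trained", "uniform", "none"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")
        if self.use_propagation:
            if self.network is None:
                raise ValueError("use_propagation=True requires a network")
            W = np.asarray(self.network, dtype=float)
            if W.shape != (p, p):
                raise ValueError(f"network shape {W.shape} does not match p={p}")
        else:
            W = None
        if self.aggregation != "none":
            if self.clusters is None:
                raise ValueError("cluster aggregation requires clusters")
            ClusterAssignment(self.clusters, p)  # validates partition
            clusters = [list(map(int, c)) for c in self.clusters]
        else:
            clusters = None
        return W, clusters

    def _penalty(self, phi, lambdas, thetas):
        """l2 penalty over *trained* blocks only."""
        r = sum(float(t @ t) for t in thetas)
        if phi is not None:
            r += float(phi @ phi)
        if lambdas is not None and self.aggregation == "trained":
            r += sum(float(l @ l) for l in lambdas)
        return r

    def fit(self, X, Y, task_names=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.shape[0] != X.shape[0]:
            raise ValueError("X must be (n_samples, p) and Y (n_samples, n_tasks)")
        n, p = X.shape
        q = Y.shape[1]
        names = list(task_names) if task_names is not None else (
            list(SUBTYPES) if q == 3 else [f"task{s}" for s in range(q)]
        )
        for s in range(q):
            pos = int(Y[:, s].sum())
            if pos == 0 or pos == n:
                raise ValueError(
                    f"subtype {names[s]!r} has a single class in the training data "
                    f"({pos}/{n} positive); cannot fit a logistic head"
                )
        W, clusters = self._validate_structure(p)
        TrainingConfig(
            learning_rate=self.learning_rate, max_iters=self.max_iter, tol=self.tol,
            delta=self.delta, phi_floor=self.phi_floor, init_phi=self.init_phi,
        )

        Xp = np.ascontiguousarray(X.T)  # p x n
        Yq = np.ascontiguousarray(Y.T).astype(float)  # q x n
        L = normalized_laplacian(W) if self.use_propagation else None

        phi = np.full(p, float(self.init_phi)) if self.use_propagation else None
        if clusters is not None:
            lambdas = [np.full(len(c), 1.0 / len(c)) for c in clusters]
            m_eff = len(clusters)
        else:
            lambdas = None
            m_eff = p
        thetas = [np.zeros(m_eff) for _ in range(q)]
        delta = float(self.delta)

        def forward_state(phi_v, lambdas_v, thetas_v):
            if phi_v is not None:
                factor = propagation_operator(L, phi_v)
                H = propagate(Xp, L, phi_v, factor=factor)
            else:
                factor, H = None, Xp
            Z = aggregate_clusters(H, clusters, lambdas_v) if lambdas_v is not None else H
            P = np.clip(expit(np.vstack([t @ Z for t in thetas_v])), EPS, 1 - EPS)
            obj = sum(bce_loss(P[s], Yq[s]) for s in range(q)) + delta * self._penalty(
                phi_v, lambdas_v, thetas_v
            )
            return factor, H, Z, P, obj

        factor, H, Z, P, obj = forward_state(phi, lambdas, thetas)
        trace = [obj]
        converged = False
        it = 0
        # per-block step sizes: grow gently after first-try successes, keep
        # the backtracked value otherwise; acceptance still requires descent,
        # so the objective trace stays monotone
        base_lr = float(self.learning_rate)
        lr_cap, lr_floor = base_lr * 1e3, base_lr * 1e-8
        lr_theta = [base_lr] * q
        lr_lambda = base_lr
        lr_phi = base_lr

        def _backtrack(lr, try_step):
            """try_step(lr) -> (accepted, payload); returns updated lr."""
            for h in range(_MAX_HALVINGS):
                if try_step(lr):
                    return min(lr * (1.3 if h == 0 else 1.0), lr_cap)
                lr = max(lr * 0.5, lr_floor)
            return lr

        for it in range(1, self.max_iter + 1):
            prev_obj = obj

            # --- theta block (heads are independent given Z)
            for s in range(q):
                g = grad_theta(Z, P[s], Yq[s], thetas[s], delta)
                base_other = obj - bce_loss(P[s], Yq[s]) - delta * float(
                    thetas[s] @ thetas[s]
                )

                def step_theta(lr, s=s, g=g, base_other=base_other):
                    nonlocal obj
                    cand = thetas[s] - lr * g
                    p_cand = np.clip(expit(cand @ Z), EPS, 1 - EPS)
                    cand_obj = base_other + bce_loss(p_cand, Yq[s]) + delta * float(
                        cand @ cand
                    )
                    if cand_obj <= obj + 1e-12:
                        thetas[s], P[s], obj = cand, p_cand, cand_obj
                        return True
                    return False

                lr_theta[s] = _backtrack(lr_theta[s], step_theta)

            # --- lambda block
            if lambdas is not None and self.aggregation == "trained":
                dZ = dloss_dZ(Z, P, Yq, thetas)
                grads = [
                    grad_lambda(dZ[k], H[np.asarray(clusters[k], dtype=int)], lambdas[k], delta)
                    for k in range(m_eff)
                ]

                def step_lambda(lr):
                    nonlocal lambdas, Z, P, obj
                    cand = [lambdas[k] - lr * grads[k] for k in range(m_eff)]
                    Z_c = aggregate_clusters(H, clusters, cand)
                    P_c = np.clip(expit(np.vstack([t @ Z_c for t in thetas])), EPS, 1 - EPS)
                    cand_obj = sum(
                        bce_loss(P_c[s], Yq[s]) for s in range(q)
                    ) + delta * self._penalty(phi, cand, thetas)
                    if cand_obj <= obj + 1e-12:
                        lambdas, Z, P, obj = cand, Z_c, P_c, cand_obj
                        return True
                    return False

                lr_lambda = _backtrack(lr_lambda, step_lambda)

            # --- phi block (projected to >= phi_floor)
            if phi is not None:
                dZ = dloss_dZ(Z, P, Yq, thetas)
                if lambdas is not None:
                    dH = backprop_to_H(dZ, clusters, lambdas, p)
                else:
                    dH = dZ
                g = grad_phi(dH, Xp, H, phi, factor, delta)

                def step_phi(lr):
                    nonlocal phi, factor, H, Z, P, obj
                    cand = np.maximum(phi - lr * g, self.phi_floor)
                    f_c, H_c, Z_c, P_c, cand_obj = forward_state(cand, lambdas, thetas)
                    if cand_obj <= obj + 1e-12:
                        phi, factor, H, Z, P, obj = cand, f_c, H_c, Z_c, P_c, cand_obj
                        return True
                    return False

                lr_phi = _backtrack(lr_phi, step_phi)

            trace.append(obj)
            if abs(prev_obj - obj) / max(1.0, abs(prev_obj)) < self.tol:
                converged = True
                break

        self.n_features_in_ = p
        self.task_names_ = names
        self.phi_ = phi
        self.lambdas_ = lambdas
        self.importances_ = (
            [np.exp(l - l.max()) / np.exp(l - l.max()).sum() for l in lambdas]
            if lambdas is not None
            else None
        )
        self.thetas_ = np.vstack(thetas)
        self.laplacian_ = L
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = it
        self.converged_ = converged
        self._clusters_idx = clusters
        return self

    # -------------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "thetas_"):
            raise AttributeError("estimator is not fitted")

    def decision_function(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must have {self.n_features_in_} columns")
        Xp = X.T
        if self.phi_ is not None:
            H = propagate(Xp, self.laplacian_, self.phi_)
        else:
            H = Xp
        Z = (
            aggregate_clusters(H, self._clusters_idx, self.lambdas_)
            if self.lambdas_ is not None
            else H
        )
        return (self.thetas_ @ Z).T  # n x q

    def predict_proba(self, X):
        """Per-subtype risks, shape (n_samples, n_tasks), strictly in (0, 1)."""
        return np.clip(expit(self.decision_function(X)), EPS, 1 - EPS)

    def predict(self, X, threshold=0.5):
        return (self.predict_proba(X) >= threshold).astype(int)

    def score(self, X, Y):
        """Mean AUROC across tasks."""
        from .metrics import auroc

        P = self.predict_proba(X)
        Y = np.asarray(Y)
        if Y.ndim == 1:
            Y = Y[:, None]
        return float(np.mean([auroc(P[:, s], Y[:, s]) for s in range(Y.shape[1])]))


def fit(
    x: ExpressionMatrix,
    net: PPINetwork,
    clusters: ClusterAssignment,
    y: SubtypeLabels,
    config: TrainingConfig | None = None,
) -> FitResult:
    """Container-level wrapper around :class:`PropagationClassifier`."""
    config = config or TrainingConfig()
    est = PropagationClassifier(
        network=net.weights,
        clusters=clusters.clusters,
        delta=config.delta,
        learning_rate=config.learning_rate,
        max_iter=config.max_iters,
        tol=config.tol,
        phi_floor=config.phi_floor,
        init_phi=config.init_phi,
    )
    est.fit(x.values.T, y.values.T, task_names=list(y.subtype_names))
    params = ModelParameters(
        phi=est.phi_,
        lambdas=est.lambdas_,
        thetas=[est.thetas_[s] for s in range(est.thetas_.shape[0])],
        delta=config.delta,
        subtype_names=tuple(y.subtype_names),
    )
    return FitResult(
        params=params,
        objective_trace=est.objective_trace_,
        converged=est.converged_,
        iterations_run=est.n_iter_,
    )
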