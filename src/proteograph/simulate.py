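"""Synthetic cohort generator built from the model's own generative
assumptions, so every pipeline stage is testable without any download.

What it emulates
----------------
* a modular PPI network: stochastic-block adjacency aligned with the
  ground-truth functional clusters, uniform edge confidences;
* DAVID-style annotation: proteins of a cluster share dedicated GO-group
  columns, with optional cross-cluster overlap columns;
* plasma-proteomic expression: each cluster is a co-expressed module driven
  by three correlated, bimodal latent pathology axes (amyloid-like burden is
  famously bimodal in elderly cohorts), plus a cluster-level factor and
  protein-level noise; rows are then z-scored and logistic-squashed exactly
  like real data;
* outcomes: the three subtype labels are Bernoulli draws from the model's own
  forward probabilities logistic(theta*' Z* + b), with per-subtype intercepts
  b tuned by bisection to hit the target prevalences (0.30 / 0.22 / 0.36,
  the cohort rates).  The fitted model has no intercept; it absorbs the
  offset through the (0, 1)-valued cluster effects.

Subtype distinctness vs. strength: the three theta* sign patterns share a
dominant severity direction but each flips two clusters (pairwise pattern dot
m-4), which gives all three subtypes near-equal logit spread while keeping
the labels distinct, positively co-occurring like the real subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .containers import (
    SUBTYPES,
    ClusterAssignment,
    ExpressionMatrix,
    IncidenceMatrix,
    ModelParameters,
    PPINetwork,
    SubtypeLabels,
)
from .graph import normalized_laplacian, propagate
from .model import aggregate_clusters


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~127 assayed proteins, 475 participants, 16
    functional clusters, subtype prevalences 0.30 / 0.22 / 0.36."""

    p: int = 127
    m: int = 16
    n: int = 475
    prevalences: tuple[float, float, float] = (0.30, 0.22, 0.36)
    within_edge_prob: float = 0.6
    between_edge_prob: float = 0.05
    weight_range: tuple[float, float] = (0.5, 1.0)
    axis_weight: float = 2.0
    follower_load: float = 0.2
    cluster_noise: float = 0.3
    protein_noise: float = 0.5
    axis_sep: float = 4.0
    axis_corr: float = 0.3
    phi_star: float = 8.0
    lambda_gap: float = 2.5
    theta_scale: float = 2.0
    noise_sd: float = 0.25
    g_per_cluster: int = 3
    overlap_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not all(0 < q < 1 for q in self.prevalences):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.within_edge_prob < self.between_edge_prob:
            raise ValueError("within-block edge probability must be >= between-block")
        if self.m < 1 or self.p < 2 * self.m or self.n < 2:
            raise ValueError(
                f"infeasible sizes: need p >= 2*m and n >= 2, got p={self.p}, "
                f"m={self.m}, n={self.n}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    network: PPINetwork
    incidence: IncidenceMatrix
    clusters: ClusterAssignment
    labels: SubtypeLabels
    params_true: ModelParameters
    intercepts: np.ndarray
    logits: np.ndarray  # 3 x n generating logits (before intercept)


def _cluster_sizes(p: int, m: int) -> list[int]:
    base, extra = divmod(p, m)
    return [base + (1 if k < extra else 0) for k in range(m)]


def _protein_ids(p):
    return [f"PROT{i:04d}" for i in range(p)]


def generate_network(cfg: SimulationConfig, rng=None):
    """Stochastic-block PPI aligned with near-equal ground-truth clusters."""
    rng = rng or np.random.default_rng(cfg.seed)
    sizes = _cluster_sizes(cfg.p, cfg.m)
    members, start = [], 0
    for sz in sizes:
        members.append(list(range(start, start + sz)))
        start += sz
    labels = np.repeat(np.arange(cfg.m), sizes)
    W = np.zeros((cfg.p, cfg.p))
    lo, hi = cfg.weight_range
    for i in range(cfg.p):
        for j in range(i + 1, cfg.p):
            prob = cfg.within_edge_prob if labels[i] == labels[j] else cfg.between_edge_prob
            if rng.random() < prob:
                W[i, j] = W[j, i] = rng.uniform(lo, hi)
    net = PPINetwork(W, _protein_ids(cfg.p))
    return net, ClusterAssignment(members, cfg.p)


def generate_incidence(
    clusters: ClusterAssignment,
    g_per_cluster: int = 3,
    overlap_rate: float = 0.0,
    seed: int = 0,
    protein_ids=None,
) -> IncidenceMatrix:
    """Cluster-shared annotation columns plus optional cross-cluster overlap."""
    if g_per_cluster < 1:
        raise ValueError("g_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    p = clusters.n_proteins
    m = clusters.m
    g = m * g_per_cluster
    inc = np.zeros((p, g), dtype=int)
    for k, members in enumerate(clusters.clusters):
        cols = range(k * g_per_cluster, (k + 1) * g_per_cluster)
        for c in cols:
            inc[members, c] = 1
            if overlap_rate > 0 and m > 1 and rng.random() < overlap_rate:
                other = rng.integers(m - 1)
                other = other if other < k else other + 1
                inc[rng.choice(clusters.clusters[other]), c] = 1
    ids = protein_ids or _protein_ids(p)
    group_ids = [f"GO_GRP{c:04d}" for c in range(g)]
    return IncidenceMatrix(inc, ids, group_ids)


def _sign_patterns(m: int, rng) -> np.ndarray:
    """(m, 3) subtype sign loadings.

    All clusters share a dominant severity direction; each deviating subtype
    flips the sign of one cluster.  The shared direction gives every subtype
    near-equal, strong logit spread, while the flipped clusters keep the
    three labels distinct and positively co-occurring, like the real
    neuropathology subtypes.
    """
    sigma = rng.choice([-1.0, 1.0], size=m)
    G = np.tile(sigma[:, None], (1, 3))
    if m >= 3:
        G[m - 2, 1] *= -1
        G[m - 1, 2] *= -1
    else:  # too few clusters for structured flips; fall back to random signs
        G = rng.choice([-1.0, 1.0], size=(m, 3)) * sigma[:, None]
    return G


def _scale_rows(V: np.ndarray) -> np.ndarray:
    sd = V.std(axis=1, ddof=1, keepdims=True)
    return expit((V - V.mean(axis=1, keepdims=True)) / sd)


def _tune_intercept(logits: np.ndarray, target: float, max_steps: int = 100) -> float:
    lo, hi = -30.0, 30.0
    f = lambda b: float(np.mean(expit(logits + b))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("prevalence target unreachable within intercept bounds")
    for _ in range(max_steps):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            return (lo + hi) / 2
    mid = (lo + hi) / 2
    if abs(f(mid)) > 0.02:
        raise RuntimeError(
            f"prevalence tuning did not converge after {max_steps} bisection steps"
        )
    return mid


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic cohort; deterministic under ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_net, rng_inc, rng_expr, rng_lab = [np.random.default_rng(c) for c in ss.spawn(4)]

    net, clusters = generate_network(cfg, rng=rng_net)
    incidence = generate_incidence(
        clusters, cfg.g_per_cluster, cfg.overlap_rate,
        seed=rng_inc.integers(2**31), protein_ids=net.protein_ids,
    )
    L = normalized_laplacian(net.weights)
    member_of = clusters.labels()

    # latent pathology axes: correlated bimodal severities
    R = np.full((3, 3), cfg.axis_corr)
    np.fill_diagonal(R, 1.0)
    copula = rng_expr.multivariate_normal(np.zeros(3), R, size=cfg.n).T
    groups = (copula > 0).astype(float)
    t = rng_expr.normal(size=(3, cfg.n)) + cfg.axis_sep * (groups - 0.5)
    t = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, ddof=1, keepdims=True)

    G = _sign_patterns(cfg.m, rng_expr)
    # the first member of each cluster is the planted driver: full axis
    # loading and top generating importance, so within-cluster importance
    # ordering is identifiable
    member_load = np.full(cfg.p, cfg.follower_load)
    for members in clusters.clusters:
        member_load[members[0]] = 1.0
    load = member_load[:, None] * (G[member_of] @ t) / np.sqrt(3)
    X0 = (
        cfg.axis_weight * load
        + cfg.cluster_noise * rng_expr.normal(size=(cfg.m, cfg.n))[member_of]
        + cfg.protein_noise * rng_expr.normal(size=(cfg.p, cfg.n))
    )
    X_clean = _scale_rows(X0)

    phi_star = np.full(cfg.p, float(cfg.phi_star))
    lambdas_star = []
    for members in clusters.clusters:
        lam = np.zeros(len(members))
        lam[0] = cfg.lambda_gap  # planted driver protein
        lambdas_star.append(lam)
    thetas_star = [cfg.theta_scale * G[:, s] for s in range(3)]

    H = propagate(X_clean, L, phi_star)
    Z = aggregate_clusters(H, clusters.clusters, lambdas_star)
    logits = np.vstack([thetas_star[s] @ Z for s in range(3)])
    intercepts = np.array(
        [_tune_intercept(logits[s], cfg.prevalences[s]) for s in range(3)]
    )
    probs = expit(logits + intercepts[:, None])
    Y = (rng_lab.random(size=probs.shape) < probs).astype(int)

    if cfg.noise_sd > 0:
        observed = _scale_rows(X0 + cfg.noise_sd * rng_expr.normal(size=X0.shape))
    else:
        observed = X_clean
    sample_ids = [f"S{j:04d}" for j in range(cfg.n)]
    expression = ExpressionMatrix(observed, net.protein_ids, sample_ids, scaled=True)
    labels = SubtypeLabels(Y, sample_ids, SUBTYPES)
    params_true = ModelParameters(
        phi=phi_star, lambdas=lambdas_star, thetas=thetas_star, delta=0.0
    )
    return SyntheticDataset(
        expression=expression,
        network=net,
        incidence=incidence,
        clusters=clusters,
        labels=labels,
        params_true=params_true,
        intercepts=intercepts,
        logits=logits,
    )
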