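"""Shared in-memory containers for expression data, networks and model state.

All numeric payloads are protein-major (``p`` proteins x ``n`` samples), the
orientation in which the propagation and aggregation algebra is written.  The
scikit-learn estimators in :mod:`proteograph.estimator` accept the usual
samples-x-features orientation and transpose at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUBTYPES = ("Abeta", "MTA", "WMH")


def _check_unique(ids, what):
    seen = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValueError(f"duplicate {what} ID {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass
class ExpressionMatrix:
    """A ``p x n`` matrix of protein expression values.

    ``scaled`` records whether :func:`proteograph.preprocessing.scale_expression`
    has been applied; the scaler refuses to run twice.
    """

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        p, n = self.values.shape
        if p != len(self.protein_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.protein_ids)} "
                f"protein IDs x {len(self.sample_ids)} sample IDs"
            )
        if p < 2 or n < 1:
            raise ValueError(f"need at least 2 proteins and 1 sample, got p={p}, n={n}")
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (impute missing data first)")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class RawExpressionMatrix:
    """Expression with missing entries allowed (NaN marks a missing cell)."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        p, n = self.values.shape
        if p != len(self.protein_ids) or n != len(self.sample_ids):
            raise ValueError("shape does not match ID lists")
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.sample_ids, "sample")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class PPINetwork:
    """Symmetric nonnegative adjacency over the ordered protein list.

    Self-interactions are zeroed on construction: STRING-style edge lists carry
    no self-loops and a nonzero diagonal would silently change the degrees.
    """

    weights: np.ndarray
    protein_ids: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.protein_ids = list(self.protein_ids)
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"adjacency must be square, got {W.shape}")
        if W.shape[0] != len(self.protein_ids):
            raise ValueError("adjacency size does not match protein ID list")
        bad = np.argwhere(W < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"negative edge weight W[{i},{j}] = {W[i, j]} "
                f"({self.protein_ids[i]}-{self.protein_ids[j]})"
            )
        asym = np.argwhere(~np.isclose(W, W.T, rtol=1e-10, atol=1e-12))
        if asym.size:
            i, j = asym[0]
            raise ValueError(f"adjacency not symmetric at W[{i},{j}] != W[{j},{i}]")
        np.fill_diagonal(self.weights, 0.0)

    @property
    def degree(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class IncidenceMatrix:
    """Binary protein x GO-group membership matrix.

    Mirrors DAVID-style functional grouping output: every protein carries at
    least one annotation (Jaccard precondition) and every group has at least
    two member proteins.
    """

    values: np.ndarray
    protein_ids: list[str]
    group_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        self.values = self.values.astype(int)
        p, g = self.values.shape
        if p != len(self.protein_ids) or g != len(self.group_ids):
            raise ValueError("incidence shape does not match ID lists")
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.group_ids, "group")
        empty_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if empty_rows.size:
            raise ValueError(
                f"protein {self.protein_ids[empty_rows[0]]} has no annotation groups"
            )
        thin_cols = np.flatnonzero(self.values.sum(axis=0) < 2)
        if thin_cols.size:
            raise ValueError(
                f"group {self.group_ids[thin_cols[0]]} has fewer than 2 member proteins"
            )


@dataclass
class ClusterAssignment:
    """A partition of protein indices into ``m`` functional clusters."""

    clusters: list[list[int]]
    n_proteins: int

    def __post_init__(self):
        self.clusters = [list(map(int, c)) for c in self.clusters]
        if len(self.clusters) < 1:
            raise ValueError("need at least one cluster")
        flat = [i for c in self.clusters for i in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters overlap")
        if sorted(flat) != list(range(self.n_proteins)):
            missing = sorted(set(range(self.n_proteins)) - set(flat))
            raise ValueError(f"clusters do not cover all proteins; missing indices {missing[:10]}")

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def labels(self) -> np.ndarray:
        """Flat label vector: ``labels()[i]`` is the cluster index of protein i."""
        lab = np.empty(self.n_proteins, dtype=int)
        for k, members in enumerate(self.clusters):
            lab[members] = k
        return lab


@dataclass
class SubtypeLabels:
    """Binary outcome matrix, one row per subtype (rows are not exclusive)."""

    values: np.ndarray
    sample_ids: list[str]
    subtype_names: tuple[str, ...] = SUBTYPES

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("labels must be 2-D (subtypes x samples)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.values = self.values.astype(int)
        if self.values.shape[0] != len(self.subtype_names):
            raise ValueError("label row count does not match subtype names")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("label column count does not match sample IDs")


@dataclass
class ModelParameters:
    """Trainable state: propagation weights phi, per-cluster importances
    lambda, and one prediction vector theta per subtype."""

    phi: np.ndarray | None
    lambdas: list[np.ndarray] | None
    thetas: list[np.ndarray]
    delta: float = 0.0
    subtype_names: tuple[str, ...] = SUBTYPES

    def __post_init__(self):
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)
            if np.any(self.phi <= 0):
                bad = int(np.argmin(self.phi))
                raise ValueError(f"phi must be strictly positive (phi[{bad}] = {self.phi[bad]})")
        if self.lambdas is not None:
            self.lambdas = [np.asarray(l, dtype=float) for l in self.lambdas]
        self.thetas = [np.asarray(t, dtype=float) for t in self.thetas]
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")

    def l2_penalty(self) -> float:
        """Sum of squared l2 norms over every active parameter block."""
        r = 0.0
        if self.phi is not None:
            r += float(self.phi @ self.phi)
        if self.lambdas is not None:
            r += float(sum(l @ l for l in self.lambdas))
        r += float(sum(t @ t for t in self.thetas))
        return r
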