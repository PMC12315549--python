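"""Readers and writers for the plain-text interchange formats.

Expression, labels and incidence travel as TSV with a protein/sample ID first
column; networks as STRING-style 3-column edge lists; cluster sets as GMT.
Numeric fields are written with 17 significant digits so write-then-read
round-trips are exact to double precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SUBTYPES,
    ClusterAssignment,
    ExpressionMatrix,
    IncidenceMatrix,
    ModelParameters,
    PPINetwork,
    RawExpressionMatrix,
    SubtypeLabels,
)

logger = logging.getLogger(__name__)

_FMT = "%.17g"


# --------------------------------------------------------------- expression

def read_expression(path) -> RawExpressionMatrix:
    """TSV with protein-ID first column, sample-ID header; empty cells and
    "NA" are missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], dtype=str)
    ids = [str(i) for i in df.index]
    dup = pd.Index(ids).duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # header is line 1
        raise ValueError(f"duplicate protein ID {ids[int(np.flatnonzero(dup)[0])]!r} at line {line}")
    values = np.empty(df.shape)
    for r, (pid, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                values[r, c] = np.nan
                continue
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} for protein {pid!r} at line {r + 2}, "
                    f"column {df.columns[c]!r}"
                ) from None
    return RawExpressionMatrix(values, ids, [str(c) for c in df.columns])


def write_expression(x, path) -> None:
    df = pd.DataFrame(x.values, index=x.protein_ids, columns=x.sample_ids)
    df.to_csv(path, sep="\t", index_label="protein", float_format=_FMT, na_rep="NA")


# ------------------------------------------------------------------ network

def read_edge_list(path, protein_ids: list[str]) -> PPINetwork:
    """3-column undirected edge list (protein_a, protein_b, weight).

    Edges touching unknown proteins are skipped with a log message; duplicate
    undirected edges are summed with a warning; self-loops are dropped.
    """
    idx = {pid: i for i, pid in enumerate(protein_ids)}
    p = len(protein_ids)
    W = np.zeros((p, p))
    seen = set()
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "w"], dtype=str,
                     comment="#", skip_blank_lines=True)
    if len(df) and df.iloc[0]["a"].lower() in ("protein_a", "protein1", "node1", "source"):
        df = df.iloc[1:]
    for line, row in enumerate(df.itertuples(index=False), start=1):
        a, b, w = row.a, row.b, float(row.w)
        if w < 0:
            raise ValueError(f"negative edge weight {w} at line {line}")
        if a == b:
            logger.warning("self-loop on %s at line %d dropped", a, line)
            continue
        if a not in idx or b not in idx:
            logger.info("edge %s-%s touches unknown protein; skipped", a, b)
            continue
        i, j = idx[a], idx[b]
        key = (min(i, j), max(i, j))
        if key in seen:
            logger.warning("duplicate edge %s-%s; weights summed", a, b)
        seen.add(key)
        W[i, j] += w
        W[j, i] += w
    return PPINetwork(W, list(protein_ids))


def write_edge_list(net: PPINetwork, path) -> None:
    rows = []
    W = net.weights
    for i in range(len(net.protein_ids)):
        for j in range(i + 1, len(net.protein_ids)):
            if W[i, j] != 0:
                rows.append((net.protein_ids[i], net.protein_ids[j], _FMT % W[i, j]))
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "weight"]).to_csv(
        path, sep="\t", index=False, header=False
    )


# ------------------------------------------------------------------ clusters

def read_clusters_gmt(path, protein_ids: list[str]) -> ClusterAssignment:
    """GMT lines (name, description, members...).  The model assumes a
    partition, so overlapping or uncovered proteins are errors."""
    idx = {pid: i for i, pid in enumerate(protein_ids)}
    clusters = []
    assigned: dict[int, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {line_no} has no members")
            name, members = parts[0], parts[2:]
            members_idx = []
            for pid in members:
                if pid not in idx:
                    logger.info("cluster %s member %s not in protein list; skipped", name, pid)
                    continue
                i = idx[pid]
                if i in assigned:
                    raise ValueError(
                        f"protein {pid} appears in clusters {assigned[i]!r} and {name!r}; "
                        "the model requires a disjoint partition"
                    )
                assigned[i] = name
                members_idx.append(i)
            if members_idx:
                clusters.append(members_idx)
    uncovered = [protein_ids[i] for i in range(len(protein_ids)) if i not in assigned]
    if uncovered:
        raise ValueError(f"proteins not covered by any cluster: {', '.join(uncovered[:10])}")
    return ClusterAssignment(clusters, len(protein_ids))


def write_clusters_gmt(clusters: ClusterAssignment, protein_ids: list[str], path,
                       names=None) -> None:
    with open(path, "w") as fh:
        for k, members in enumerate(clusters.clusters):
            name = names[k] if names else f"cluster{k}"
            ids = [protein_ids[i] for i in members]
            fh.write("\t".join([name, f"n={len(ids)}"] + ids) + "\n")


# ------------------------------------------------------------------- labels

def read_labels(path) -> SubtypeLabels:
    """TSV: sample-ID first column, one binary column per subtype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SubtypeLabels(
        df.to_numpy().T, [str(i) for i in df.index], tuple(str(c) for c in df.columns)
    )


def write_labels(labels: SubtypeLabels, path) -> None:
    pd.DataFrame(
        labels.values.T, index=labels.sample_ids, columns=list(labels.subtype_names)
    ).to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- incidence

def read_incidence(path) -> IncidenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IncidenceMatrix(
        df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_incidence(inc: IncidenceMatrix, path) -> None:
    pd.DataFrame(inc.values, index=inc.protein_ids, columns=inc.group_ids).to_csv(
        path, sep="\t", index_label="protein"
    )


# -------------------------------------------------------------- predictions

def write_predictions(sample_ids, probs: np.ndarray, path, subtype_names=SUBTYPES) -> None:
    """Predictions TSV: sample ID plus one risk column per subtype."""
    cols = {f"risk_{name}": probs[:, s] for s, name in enumerate(subtype_names)}
    pd.DataFrame(cols, index=list(sample_ids)).to_csv(
        path, sep="\t", index_label="sample", float_format=_FMT
    )


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -------------------------------------------------------------- model file

def write_model(path, params: ModelParameters, protein_ids, clusters: ClusterAssignment,
                config=None, objective_trace=None) -> None:
    """Serialize a fitted model as a structured text document."""
    import json

    doc = {
        "protein_ids": list(protein_ids),
        "clusters": [list(map(int, c)) for c in clusters.clusters],
        "phi": None if params.phi is None else params.phi.tolist(),
        "lambdas": None if params.lambdas is None else [l.tolist() for l in params.lambdas],
        "thetas": [t.tolist() for t in params.thetas],
        "delta": params.delta,
        "subtype_names": list(params.subtype_names),
        "config": None if config is None else vars(config),
        "objective_trace": None if objective_trace is None else list(map(float, objective_trace)),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path):
    import json

    doc = json.loads(Path(path).read_text())
    params = ModelParameters(
        phi=None if doc["phi"] is None else np.asarray(doc["phi"]),
        lambdas=None if doc["lambdas"] is None else [np.asarray(l) for l in doc["lambdas"]],
        thetas=[np.asarray(t) for t in doc["thetas"]],
        delta=doc["delta"],
        subtype_names=tuple(doc["subtype_names"]),
    )
    clusters = ClusterAssignment(doc["clusters"], len(doc["protein_ids"]))
    return params, doc["protein_ids"], clusters, doc
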