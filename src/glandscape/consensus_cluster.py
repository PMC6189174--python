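"""Replicate-consensus clustering, k selection and group-stability scoring.

Each simulated technical replicate is re-normalised (TPM on the retained gene
set, then log2(x+1)), cells are clustered by average-linkage hierarchical
clustering on the distance 1 − Spearman correlation, and the consensus matrix
records the frequency with which each pair of cells lands in the same cluster
across replicates. The cluster number k is chosen from the distribution of
cluster-wise mean silhouette widths pooled over all replicates (the suggested
k maximises the pooled median; the full distributions are returned so a final
choice can be made manually). Final clusters come from cutting an
average-linkage tree on 1 − consensus.

A cell grouping is scored against the consensus matrix by
``stability − promiscuity``: the mean co-clustering frequency within the
group minus the mean frequency between group members and all other cells.
A grouping whose members always co-cluster and never co-cluster with
outsiders scores 1; random groupings score about 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_samples

from .errors import UnitError
from .matrix_io import CountMatrix, ExpressionMatrix
from .noise_replicates import ReplicateSet
from .qc_normalize import log2_tpm, tpm


@dataclass
class ClusterLabels:
    """Cell → cluster-index assignment (clusters numbered 0..k−1)."""

    labels: pd.Series
    k: int


@dataclass
class ConsensusMatrix:
    """Symmetric cell × cell co-clustering frequencies with unit diagonal."""

    matrix: pd.DataFrame

    def __post_init__(self):
        arr = self.matrix.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")

    @property
    def cells(self) -> pd.Index:
        return self.matrix.index


@dataclass
class KSelection:
    """Pooled cluster-wise mean silhouette widths per k, and the argmax-median k."""

    silhouettes: dict[int, list[float]]
    suggested_k: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "k": k,
                "n_values": len(v),
                "median_silhouette": float(np.median(v)) if v else np.nan,
                "mean_silhouette": float(np.mean(v)) if v else np.nan,
            }
            for k, v in sorted(self.silhouettes.items())
        ]
        return pd.DataFrame(rows).set_index("k")


@dataclass
class GroupScore:
    """Per-group stability/promiscuity/score table and their mean."""

    per_group: pd.DataFrame
    mean_score: float


# -- distances and clustering ---------------------------------------------


def spearman_distance(expr_values: np.ndarray) -> np.ndarray:
    """1 − Spearman correlation between cells (columns), zero diagonal."""
    ranks = rankdata(expr_values, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _first_appearance_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k−1 in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _linkage_from_distance(d: np.ndarray) -> np.ndarray:
    return sch.linkage(squareform(d, checks=False), method="average")


def _cut(linkage: np.ndarray, k: int) -> np.ndarray:
    raw = sch.fcluster(linkage, t=k, criterion="maxclust")
    return _first_appearance_labels(raw)


def cluster_cells(expr: ExpressionMatrix, k: int) -> ClusterLabels:
    """Average-linkage hierarchical clustering on 1 − Spearman, cut to k clusters."""
    if expr.unit != "log2TPM":
        raise UnitError(f"expected log2TPM, got {expr.unit}")
    n = expr.values.shape[1]
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        d = spearman_distance(expr.values.to_numpy())
        labels = _cut(_linkage_from_distance(d), k)
    return ClusterLabels(
        labels=pd.Series(labels, index=expr.values.columns, name="cluster"),
        k=int(labels.max()) + 1,
    )


def consensus_from_labels(labelings: list[ClusterLabels]) -> ConsensusMatrix:
    """C_ij = fraction of labelings in which cells i and j share a cluster."""
    if len(labelings) < 2:
        raise ValueError("need at least 2 labelings")
    cells = labelings[0].labels.index
    acc = np.zeros((len(cells), len(cells)))
    for lab in labelings:
        if not lab.labels.index.equals(cells):
            raise ValueError("labelings cover different cell sets")
        v = lab.labels.to_numpy()
        acc += (v[:, None] == v[None, :]).astype(float)
    c = acc / len(labelings)
    np.fill_diagonal(c, 1.0)
    return ConsensusMatrix(pd.DataFrame(c, index=cells, columns=cells))


# -- the replicate loop ---------------------------------------------------


def _prepare_replicate(rep: CountMatrix, genes) -> np.ndarray:
    """Per-replicate normalization: TPM on the retained genes, then log2(x+1)."""
    lengths = rep.gene_table["length_bp"].to_dict()
    expr = tpm(rep, lengths, genes=genes)
    return log2_tpm(expr).values.to_numpy()


def _cluster_silhouettes(d: np.ndarray, labels: np.ndarray) -> list[float]:
    """Cluster-wise mean silhouette widths; singleton clusters contribute 0."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return [0.0 for _ in uniq]
    sil = silhouette_samples(d, labels, metric="precomputed")
    out = []
    for c in uniq:
        members = labels == c
        out.append(0.0 if members.sum() == 1 else float(sil[members].mean()))
    return out


def choose_k(
    replicates: ReplicateSet,
    k_range,
    genes=None,
) -> KSelection:
    """Silhouette-based k selection over the replicate set.

    For each replicate and each k, cells are clustered and the per-cluster
    mean silhouette widths (on the same Spearman distance) are pooled. The
    suggested k maximises the median pooled value; the full distributions are
    kept so k can also be chosen by inspection.
    """
    k_range = sorted(set(int(k) for k in k_range))
    n = replicates.source.n_cells
    if not k_range:
        raise ValueError("empty k range")
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    if genes is None:
        genes = replicates.source.values.index[~replicates.source.spike_mask.to_numpy()]
    pooled: dict[int, list[float]] = {k: [] for k in k_range}
    for rep in replicates:
        values = _prepare_replicate(rep, genes)
        d = spearman_distance(values)
        linkage = _linkage_from_distance(d)
        for k in k_range:
            labels = _cut(linkage, k)
            pooled[k].extend(_cluster_silhouettes(d, labels))
    medians = {k: np.median(v) if v else -np.inf for k, v in pooled.items()}
    suggested = max(medians, key=lambda k: (medians[k], -k))
    return KSelection(silhouettes=pooled, suggested_k=int(suggested))


def replicate_labelings(replicates: ReplicateSet, k: int, genes=None) -> list[ClusterLabels]:
    """Cluster every replicate at a fixed k (input to the consensus matrix)."""
    if genes is None:
        genes = replicates.source.values.index[~replicates.source.spike_mask.to_numpy()]
    cells = replicates.source.values.columns
    out = []
    for rep in replicates:
        values = _prepare_replicate(rep, genes)
        labels = _cut(_linkage_from_distance(spearman_distance(values)), k)
        out.append(
            ClusterLabels(labels=pd.Series(labels, index=cells, name="cluster"), k=k)
        )
    return out


def final_clusters(consensus: ConsensusMatrix, k: int) -> ClusterLabels:
    """Average-linkage clustering of 1 − consensus, cut at k."""
    n = len(consensus.cells)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    d = 1.0 - consensus.matrix.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    labels = np.zeros(n, dtype=int) if k == 1 else _cut(_linkage_from_distance(d), k)
    return ClusterLabels(
        labels=pd.Series(labels, index=consensus.cells, name="cluster"),
        k=int(labels.max()) + 1,
    )


def group_score(consensus: ConsensusMatrix, groups: dict) -> GroupScore:
    """Stability − promiscuity per group against the consensus matrix.

    ``groups`` maps cell_id → group name over the consensus cells. A single
    group covering all cells (an "ensemble" grouping) has promiscuity 0 by
    convention.
    """
    cells = list(consensus.cells)
    missing = [c for c in cells if c not in groups]
    if missing:
        raise ValueError(f"cells without a group: {missing[:5]}")
    arr = consensus.matrix.to_numpy()
    names = sorted(set(groups[c] for c in cells), key=str)
    member_idx = {
        g: np.array([i for i, c in enumerate(cells) if groups[c] == g]) for g in names
    }
    for g, idx in member_idx.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
    rows = []
    for g in names:
        idx = member_idx[g]
        within = arr[np.ix_(idx, idx)]
        off = within[~np.eye(len(idx), dtype=bool)]
        stability = float(off.mean())
        outside = np.setdiff1d(np.arange(len(cells)), idx)
        promiscuity = float(arr[np.ix_(idx, outside)].mean()) if outside.size else 0.0
        rows.append(
            {
                "group": g,
                "n_cells": len(idx),
                "stability": stability,
                "promiscuity": promiscuity,
                "score": stability - promiscuity,
            }
        )
    per_group = pd.DataFrame(rows).set_index("group")
    return GroupScore(per_group=per_group, mean_score=float(per_group["score"].mean()))
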