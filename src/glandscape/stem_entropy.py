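"""Transcriptome entropy, inter-cluster links and the stem score.

The stem score flags progenitor-like clusters: a multipotent cell tends to
express a broad, flat transcriptome (high entropy) and to sit between the
differentiated expression states it can reach (many inter-cluster links).

Entropy of a cell is the Shannon entropy of its TPM composition,
H = −Σ p_g ln p_g / ln G with p_g = TPM_g / 1e6, normalised by the number of
retained genes G so H ∈ [0, 1] is comparable across panel sizes.

Links are declared from a medoid geometry in log2TPM space: each cell is
projected onto the segments joining its cluster's medoid to every other
medoid; the cell supports a link toward the cluster with the largest scalar
projection if that projection falls strictly between the two medoids. A link
between clusters exists when it receives enough supporting cells from either
side. The score of a cluster is its number of links times the excess of its
median entropy over the lowest cluster-median entropy, so a cluster at
minimum entropy or with no links scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus_cluster import ClusterLabels, spearman_distance
from .errors import UnitError
from .matrix_io import ExpressionMatrix


@dataclass
class EntropyVector:
    """Per-cell normalized transcriptome entropy in [0, 1]."""

    values: pd.Series


@dataclass
class LinkGraph:
    clusters: list[int]
    support: pd.DataFrame  # directed support counts, rows a → columns b
    links: set[frozenset]
    links_per_cluster: dict[int, int]
    m_min: dict[int, int]


@dataclass
class StemScores:
    table: pd.DataFrame  # index cluster; median_entropy, delta_entropy, n_links, score


def cell_entropy(expr: ExpressionMatrix) -> EntropyVector:
    """Normalized Shannon entropy of each cell's TPM composition."""
    if expr.unit != "TPM":
        raise UnitError(f"expected TPM, got {expr.unit}")
    values = expr.values.to_numpy(dtype=float)
    n_genes = values.shape[0]
    if n_genes < 2:
        raise ValueError("need at least 2 genes for entropy")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = expr.values.columns[totals <= 0].tolist()
        raise ValueError(f"cells with zero total expression: {bad[:5]}")
    p = values / totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0) / np.log(n_genes)
    return EntropyVector(pd.Series(np.clip(h, 0.0, 1.0), index=expr.values.columns, name="entropy"))


def _medoid_index(d: np.ndarray, members: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def cluster_links(
    expr: ExpressionMatrix, labels: ClusterLabels, m_min: int | None = None
) -> LinkGraph:
    """Medoid-projection link graph between clusters in log2TPM space.

    ``m_min`` is the minimum number of supporting cells for a link; by default
    it is per-cluster, max(2, ceil(1% of cluster size)). A link {a, b} exists
    when either direction reaches its threshold.
    """
    if expr.unit != "log2TPM":
        raise UnitError(f"expected log2TPM, got {expr.unit}")
    lab = labels.labels.loc[expr.values.columns].to_numpy()
    clusters = sorted(set(int(v) for v in lab))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for links")

    values = expr.values.to_numpy(dtype=float)
    d = spearman_distance(values)
    medoid = {c: _medoid_index(d, np.where(lab == c)[0]) for c in clusters}
    medoid_vec = {c: values[:, medoid[c]] for c in clusters}

    support = pd.DataFrame(0, index=clusters, columns=clusters)
    for a in clusters:
        members = np.where(lab == a)[0]
        others = [b for b in clusters if b != a]
        dirs, norms = [], []
        for b in others:
            v = medoid_vec[b] - medoid_vec[a]
            dirs.append(v)
            norms.append(float(v @ v))
        for i in members:
            best_b, best_t = None, -np.inf
            x = values[:, i] - medoid_vec[a]
            for b, v, n2 in zip(others, dirs, norms):
                if n2 <= 0:
                    continue  # coincident medoids: no direction
                t = float(x @ v) / n2
                if t > best_t:
                    best_b, best_t = b, t
            if best_b is not None and 0.0 < best_t < 1.0:
                support.loc[a, best_b] += 1

    sizes = {c: int((lab == c).sum()) for c in clusters}
    thresholds = {
        c: (m_min if m_min is not None else max(2, int(np.ceil(0.01 * sizes[c]))))
        for c in clusters
    }
    links = set()
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            if support.loc[a, b] >= thresholds[a] or support.loc[b, a] >= thresholds[b]:
                links.add(frozenset((a, b)))
    links_per_cluster = {c: sum(1 for l in links if c in l) for c in clusters}
    return LinkGraph(
        clusters=clusters,
        support=support,
        links=links,
        links_per_cluster=links_per_cluster,
        m_min=thresholds,
    )


def stem_scores(entropy: EntropyVector, labels: ClusterLabels, graph: LinkGraph) -> StemScores:
    """score_c = n_links(c) × (median entropy in c − minimum cluster-median entropy)."""
    lab = labels.labels
    rows = []
    for c in graph.clusters:
        members = lab.index[lab == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        rows.append(
            {"cluster": c, "median_entropy": float(entropy.values.loc[members].median())}
        )
    table = pd.DataFrame(rows).set_index("cluster")
    min_h = table["median_entropy"].min()
    table["delta_entropy"] = table["median_entropy"] - min_h
    table["n_links"] = [graph.links_per_cluster[c] for c in table.index]
    table["score"] = table["n_links"] * table["delta_entropy"]
    return StemScores(table=table)
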