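"""Instance-level classifier agreement, hierarchical clustering, Newick export.

Two classifiers' agreement is the fraction of commonly covered pairs on
which they emit the same predicted label, irrespective of gold.  Clustering
agglomerates on the dissimilarity 1 - agreement; since that quantity need
not satisfy the triangle inequality, only metric-free linkage criteria
(complete, average, single) are offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import PredictionSet, ValidationError

__all__ = [
    "pairwise_agreement",
    "agreement_matrix",
    "LinkageTree",
    "cluster",
    "to_newick",
]


def pairwise_agreement(
    predictions: PredictionSet, c1: str, c2: str
) -> float:
    """Fraction of common pairs on which c1 and c2 predict identically."""
    col1 = predictions.column(c1)
    col2 = predictions.column(c2)
    common = col1.keys() & col2.keys()
    if not common:
        raise ValidationError(f"{c1} and {c2} share no covered pairs")
    same = sum(col1[pid] == col2[pid] for pid in common)
    return same / len(common)


def agreement_matrix(predictions: PredictionSet) -> pd.DataFrame:
    """Symmetric roster-by-roster agreement matrix (diagonal 1)."""
    roster = sorted(predictions.roster)
    if len(roster) < 2:
        raise ValidationError("need at least two classifiers")
    cols = {c: predictions.column(c) for c in roster}
    ids = sorted(set.intersection(*(set(v) for v in cols.values())))
    arr = np.array([[cols[c][pid] for pid in ids] for c in roster], dtype=bool)
    n = len(roster)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = np.mean(arr[i] == arr[j])
    return pd.DataFrame(mat, index=roster, columns=roster)


@dataclass
class LinkageTree:
    """Agglomerative merge tree over the roster in 1 - agreement distance."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    method: str

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def cluster(matrix: pd.DataFrame, linkage: str = "complete") -> LinkageTree:
    """Hierarchical clustering of the agreement matrix.

    Classifiers are ordered lexicographically before linkage so that ties
    resolve deterministically.
    """
    if len(matrix) < 2:
        raise ValidationError("need at least two classifiers to cluster")
    if linkage not in ("complete", "average", "single"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    labels = sorted(matrix.index)
    dist = 1.0 - matrix.loc[labels, labels].to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return LinkageTree(labels=list(labels), linkage=Z, method=linkage)


def _quote_label(name: str) -> str:
    if any(ch in name for ch in "()[]{}:;,='\" \t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: LinkageTree) -> str:
    """Serialize the merge tree as Newick with height-difference branch lengths."""
    n = len(tree.labels)
    heights = {i: 0.0 for i in range(n)}
    texts = {i: _quote_label(tree.labels[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(tree.linkage):
        a, b = int(a), int(b)
        node = n + k
        parts = []
        for child in (a, b):
            branch = h - heights[child]
            parts.append(f"{texts[child]}:{branch:.6g}")
        texts[node] = "(" + ",".join(parts) + ")"
        heights[node] = float(h)
    return texts[n + len(tree.linkage) - 1] + ";"
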