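"""Correlation-distance Ward clustering with bootstrap subcluster support.

Samples (tumor profiles) are compared by d = 1 - Pearson r and agglomerated
with Ward's minimum-variance criterion in its ward.D2 dialect (squared
dissimilarities inside the Lance-Williams update, heights on the distance
scale). Matched initial/recurrent pairs can be classified by whether they
merge as direct neighbors, and node stability is assessed by a plain feature
bootstrap (fraction of replicate trees reproducing each node's leaf set).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator


def corr_distance(X: np.ndarray, sample_ids=None) -> np.ndarray:
    """1 - Pearson correlation between rows of a samples x features matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 features per sample")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(sample_ids[i]) for i in bad] if sample_ids is not None else bad.tolist()
        )
        raise ValueError(f"constant (zero-variance) sample vector(s): {names}")
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    # numerical symmetry / clipping into [0, 2]
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return D


def ward_tree(D: np.ndarray) -> np.ndarray:
    """ward.D2 linkage matrix (scipy format) from a square distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return hierarchy.linkage(squareform(D, checks=False), method="ward")


def cut_major_clusters(Z: np.ndarray, k: int, sample_ids=None) -> pd.Series:
    """Cut the dendrogram into exactly k clusters (removing the k-1 top merges).

    Labels are renumbered 1..k in order of first appearance along the leaf
    order, so they are deterministic across platforms.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if np.unique(raw).size != k:
        raise ValueError("tied merge heights prevent an exact k-cluster cut")
    order = hierarchy.leaves_list(Z)
    relabel: dict[int, int] = {}
    for leaf in order:
        relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
    labels = np.array([relabel[int(c)] for c in raw])
    index = sample_ids if sample_ids is not None else np.arange(n)
    return pd.Series(labels, index=index, name="cluster")


def node_leafsets(Z: np.ndarray) -> list[frozenset[int]]:
    """Leaf-index set of every internal node, in merge order."""
    n = Z.shape[0] + 1
    sets: list[frozenset[int]] = []
    store: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    for row in range(Z.shape[0]):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        s = store[a] | store[b]
        store[n + row] = s
        sets.append(s)
    return sets


def matched_pair_adjacency(
    Z: np.ndarray, pairs, sample_ids, k: int = 3
) -> pd.DataFrame:
    """Classify each (initial, recurrent) pair's position in the dendrogram.

    A pair is "direct" iff some internal node's leaf set is exactly the two
    samples; otherwise it is "same-cluster" or "different-cluster" at the
    k-cluster cut.
    """
    ids = list(sample_ids)
    pos = {s: i for i, s in enumerate(ids)}
    sets = set(node_leafsets(Z))
    labels = cut_major_clusters(Z, k, sample_ids=ids)
    rows = []
    for initial, recurrent in pairs:
        for s in (initial, recurrent):
            if s not in pos:
                raise KeyError(f"unknown sample id {s!r}")
        if frozenset((pos[initial], pos[recurrent])) in sets:
            status = "direct"
        elif labels[initial] == labels[recurrent]:
            status = "same-cluster"
        else:
            status = "different-cluster"
        rows.append((initial, recurrent, status))
    return pd.DataFrame(rows, columns=["initial", "recurrent", "status"])


def bootstrap_support(
    X: np.ndarray, Z: np.ndarray, B: int = 100, seed: int = 0
) -> np.ndarray:
    """Plain bootstrap probability of each internal node of Z.

    Features (columns) are resampled with replacement B times; each
    replicate is re-clustered and a node is supported by the replicate if
    its exact leaf set appears in the replicate tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    original = node_leafsets(Z)
    hits = np.zeros(len(original))
    for _ in range(B):
        cols = rng.integers(0, X.shape[1], size=X.shape[1])
        Zb = ward_tree(corr_distance(X[:, cols]))
        found = set(node_leafsets(Zb))
        hits += np.fromiter((s in found for s in original), dtype=float)
    return hits / B


class WardCorrelationClustering(BaseEstimator):
    """Hierarchical clustering of sample profiles, sklearn-style.

    Parameters
    ----------
    n_clusters : number of major clusters for :meth:`fit_predict`.

    Attributes (after :meth:`fit`)
    ------------------------------
    distance_ : square 1 - Pearson distance matrix.
    linkage_ : scipy linkage matrix (ward.D2).
    labels_ : cluster labels at the n_clusters cut.
    sample_ids_ : row identifiers used for reporting.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None, sample_ids=None):
        X = np.asarray(X, dtype=float)
        self.sample_ids_ = (
            list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
        )
        self._X = X
        self.distance_ = corr_distance(X, sample_ids=self.sample_ids_)
        self.linkage_ = ward_tree(self.distance_)
        self.labels_ = cut_major_clusters(
            self.linkage_, self.n_clusters, sample_ids=self.sample_ids_
        )
        return self

    def fit_predict(self, X, y=None, sample_ids=None):
        return self.fit(X, sample_ids=sample_ids).labels_.to_numpy()

    def pair_adjacency(self, pairs, k: int | None = None) -> pd.DataFrame:
        return matched_pair_adjacency(
            self.linkage_, pairs, self.sample_ids_, k=k or self.n_clusters
        )

    def bootstrap_support(self, B: int = 100, seed: int = 0) -> np.ndarray:
        return bootstrap_support(self._X, self.linkage_, B=B, seed=seed)
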