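"""Community dissimilarities, nMDS ordination, and UPGMA clustering.

Three dissimilarity conventions are fixed here once and used everywhere
downstream:

* Bray-Curtis  ``sum|x-y| / sum(x+y)`` — abundance-weighted, robust to
  singletons;
* Jaccard      ``1 - |A∩B| / |A∪B|`` on presence/absence — purely
  qualitative membership;
* Canberra     ``(1/NZ) sum |x-y| / (x+y)`` over the NZ positions where
  x+y > 0 — weights every OTU equally, so rare taxa dominate. Normalising
  by the nonzero-pair count (the "weighted Canberra" of common ecology
  software) keeps values in [0, 1] and comparable across pairs; the raw-sum
  variant sits behind ``normalized=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .containers import CountTable, ValidationError

__all__ = [
    "bray_curtis",
    "jaccard",
    "canberra",
    "distance_matrix",
    "Ordination",
    "nmds",
    "Dendrogram",
    "hclust_average",
    "to_newick",
    "METRICS",
]


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValidationError("both vectors are all-zero")
    return x, y


def bray_curtis(x, y) -> float:
    x, y = _check_pair(x, y)
    return float(_sp_braycurtis(x, y))


def jaccard(x, y) -> float:
    x, y = _check_pair(x, y)
    a, b = x > 0, y > 0
    union = np.count_nonzero(a | b)
    return 1.0 - np.count_nonzero(a & b) / union


def canberra(x, y, normalized: bool = True) -> float:
    x, y = _check_pair(x, y)
    s = x + y
    nz = s > 0
    terms = np.abs(x[nz] - y[nz]) / s[nz]
    return float(terms.sum() / np.count_nonzero(nz)) if normalized else float(terms.sum())


METRICS = {"braycurtis": bray_curtis, "jaccard": jaccard, "canberra": canberra}


def distance_matrix(counts: CountTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Pairwise dissimilarities between all sample columns of a table."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if counts.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    fn = METRICS[metric]
    ids = counts.sample_ids
    n = len(ids)
    d = np.zeros((n, n))
    cols = counts.counts.T.astype(float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(cols[i], cols[j])
    return DistanceMatrix(d, ids)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray      # n x k
    stress: float                # Kruskal stress-1
    n_restarts: int
    seed: int


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> Ordination:
    """Nonmetric MDS: minimise Kruskal stress-1 with isotonic regression of
    embedded distances on the input dissimilarities; best of ``n_restarts``
    random initialisations is returned."""
    if dm.shape[0] < 3:
        raise ValidationError("nMDS needs at least 3 samples")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.data)
    return Ordination(list(dm.ids), coords, float(model.stress_), n_restarts, seed)


@dataclass
class Dendrogram:
    """UPGMA merge history: (node_a, node_b, height) triples in scipy's
    node numbering (leaves 0..n-1, merge i creates node n+i)."""

    ids: list[str]
    merges: list[tuple[int, int, float]]
    leaf_order: list[str]
    linkage_matrix: np.ndarray


def hclust_average(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix."""
    z = linkage(squareform(dm.data, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    order = [dm.ids[i] for i in leaves_list(z)]
    return Dendrogram(list(dm.ids), merges, order, z)


def to_newick(dendro: Dendrogram) -> str:
    """Serialise the dendrogram as Newick; branch lengths are half the height
    difference between a node and its parent (UPGMA trees are ultrametric)."""
    root = to_tree(dendro.linkage_matrix)

    def walk(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{dendro.ids[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"
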