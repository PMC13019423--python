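"""PCA exploration and hierarchical clustering.

Turns the usual multivariate-figure content into data tables: biplot
extraction of the wavenumbers contributing most to a PC pair, per-group
variance ellipses, leave-one-out nearest-centroid discrimination in a
score plane, and Ward-linkage agglomerative clustering with a k-cluster
cut scored by label purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .qc import PCAModel

__all__ = [
    "BiplotSummary",
    "DendrogramCut",
    "biplot_summary",
    "pairwise_score_discrimination",
    "hca",
    "cut_tree",
    "tree_to_newick",
]


@dataclass
class BiplotSummary:
    pc_pair: tuple
    scores: np.ndarray                 # n×2
    loadings: np.ndarray               # p×2
    top_bands: list                    # [(wavenumber, magnitude)] descending
    variance_ellipses: dict            # group -> (mean(2), cov 2×2)


def biplot_summary(
    model: PCAModel, pc_pair: tuple[int, int], labels, wavenumbers
) -> BiplotSummary:
    """Scores/loadings for one PC pair, wavenumbers ranked by loading
    magnitude, and per-group score means and covariances."""
    for pc in pc_pair:
        if not (0 <= pc < model.n_components):
            raise ValueError(f"PC index {pc} outside retained components")
    wn = np.asarray(wavenumbers, dtype=float)
    scores = model.scores[:, list(pc_pair)]
    loadings = model.loadings[:, list(pc_pair)]
    mag = np.linalg.norm(loadings, axis=1)
    order = np.argsort(-mag, kind="stable")
    top = [(float(wn[j]), float(mag[j])) for j in order]
    labels = np.asarray(labels, dtype=object)
    ellipses = {}
    for g in dict.fromkeys(labels):
        pts = scores[labels == g]
        cov = np.cov(pts, rowvar=False) if pts.shape[0] > 1 else np.zeros((2, 2))
        ellipses[g] = (pts.mean(axis=0), cov)
    return BiplotSummary(tuple(pc_pair), scores, loadings, top, ellipses)


def pairwise_score_discrimination(
    model: PCAModel, labels, pc_pair: tuple[int, int] = (0, 1)
) -> float:
    """Leave-one-out nearest-centroid accuracy in the chosen score plane.

    This is the operational reading of "% discrimination" for a PC pair:
    deterministic, and monotone in class separation.
    """
    labels = np.asarray(labels, dtype=object)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    scores = model.scores[:, list(pc_pair)]
    sums = {g: scores[labels == g].sum(axis=0) for g in groups}
    counts = {g: int((labels == g).sum()) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError("every group needs at least 2 members for LOO centroids")
    correct = 0
    for i, (x, lab) in enumerate(zip(scores, labels)):
        best, best_d = None, np.inf
        for g in groups:
            if g == lab:
                cen = (sums[g] - x) / (counts[g] - 1)
            else:
                cen = sums[g] / counts[g]
            d = float(np.sum((x - cen) ** 2))
            if d < best_d:
                best, best_d = g, d
        correct += best == lab
    return correct / labels.size


def hca(data: np.ndarray, linkage: str = "ward", metric: str = "euclidean") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) over rows of ``data``."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    valid_linkage = {"single", "complete", "average", "weighted", "centroid", "median", "ward"}
    if linkage not in valid_linkage:
        raise ValueError(f"unknown linkage {linkage!r}")
    try:
        d = pdist(X, metric=metric)
    except ValueError as e:
        raise ValueError(f"unknown metric {metric!r}: {e}") from None
    return hierarchy.linkage(d, method=linkage)


@dataclass
class DendrogramCut:
    tree: np.ndarray
    k: int
    assignments: np.ndarray
    purity: float
    majority_labels: dict              # cluster id -> majority group label


def cut_tree(tree: np.ndarray, k: int, labels) -> DendrogramCut:
    """Cut the merge tree into k clusters (undoing the last k−1 merges)
    and score cluster purity against the given group labels."""
    n = tree.shape[0] + 1
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    assign = hierarchy.cut_tree(tree, n_clusters=k).ravel()
    labels = np.asarray(labels, dtype=object)
    majority: dict = {}
    correct = 0
    for cid in np.unique(assign):
        members = labels[assign == cid]
        vals, counts = np.unique(members.astype(str), return_counts=True)
        maj = vals[np.argmax(counts)]
        majority[int(cid)] = maj
        correct += int(np.sum(members.astype(str) == maj))
    return DendrogramCut(tree, k, assign, correct / labels.size, majority)


def _newick(node, leaf_names, parent_height) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{leaf_names[node.id]}:{length:.10g}"
    left = _newick(node.left, leaf_names, node.dist)
    right = _newick(node.right, leaf_names, node.dist)
    return f"({left},{right}):{length:.10g}"


def tree_to_newick(tree: np.ndarray, leaf_names) -> str:
    """Serialise the merge tree as Newick with heights as branch lengths."""
    root = hierarchy.to_tree(tree)
    names = [str(x) for x in leaf_names]
    inner = _newick(root, names, root.dist)
    return inner.rsplit(":", 1)[0] + ";"
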