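"""Clustering the fused network and attributing clusters to dominant features.

Conditions are grouped by spectral clustering of the fused similarity
matrix (normalized-Laplacian embedding + k-means).  The resulting labels
are then explained by a small classification tree over the feature matrix
(typically the flux matrix): a tree limited to a handful of split rules
names the features whose values best separate the clusters, together with
their split thresholds and Gini importances.  Bootstrap resampling of the
conditions checks that those features are stably selected rather than
artefacts of particular conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.cluster import SpectralClustering
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .fusion import SimilarityLayer

__all__ = [
    "ClusterAssignment",
    "AttributionReport",
    "spectral_cluster",
    "attribute_clusters",
    "bootstrap_stability",
    "export_ordered_matrix",
    "DecisionTreeAttributor",
]


@dataclass
class ClusterAssignment:
    """Per-condition labels 1..k plus the grouped export ordering."""

    labels: np.ndarray
    k: int
    ordering: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("labels must be contiguous from 1")


@dataclass
class AttributionReport:
    """Tree-based attribution of clusters to features.

    ``importances`` are Gini importances (sum <= 1 over reported features);
    ``split_thresholds`` maps each used feature to its split threshold(s);
    ``accuracy`` is training accuracy of the limited-depth tree; ``stability``
    (when bootstrapped) is the fraction of resamples in which a feature was
    among the top split features.
    """

    features: list[str]
    importances: np.ndarray
    split_thresholds: dict[str, list[float]]
    accuracy: float
    n_rules: int
    stability: dict[str, float] = field(default_factory=dict)

    def top_feature(self) -> str:
        return self.features[int(np.argmax(self.importances))]


def spectral_cluster(
    fused: SimilarityLayer | np.ndarray,
    k: int,
    seed: int = 0,
) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of a similarity matrix.

    Deterministic given ``seed`` (k-means initialization).  If the graph has
    more connected components than k a warning is issued and labels are
    still returned.  Labels are renumbered 1..k in order of first
    appearance; the export ordering groups conditions by label.
    """
    if isinstance(fused, SimilarityLayer):
        W = fused.matrix
        node_ids = list(fused.node_ids)
    else:
        W = np.asarray(fused, dtype=float)
        node_ids = [str(i) for i in range(W.shape[0])]
    n = W.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        labels = np.ones(n, dtype=int)
        return ClusterAssignment(labels, 1, np.arange(n), node_ids)
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > k:
        warnings.warn(
            f"similarity graph has {n_comp} components but k={k}", stacklevel=2
        )
    sc = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
    )
    raw = sc.fit_predict(W)
    # renumber by first appearance so labels are stable under relabeling
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    ordering = np.argsort(labels, kind="stable")
    return ClusterAssignment(labels, k, ordering, node_ids)


class DecisionTreeAttributor(BaseEstimator):
    """A small CART tree that names the features separating the clusters.

    ``max_rules`` caps the number of internal split nodes (a tree with two
    rules has three leaves).  Fit on a conditions x features matrix ``X``
    and cluster labels ``y``; fitted attributes: ``report_``,
    ``importances_``, ``accuracy_``, ``tree_``.
    """

    def __init__(self, max_rules: int = 2, random_state: int | None = 0):
        self.max_rules = max_rules
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("attribution needs at least two clusters")
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=self.max_rules + 1,
            random_state=self.random_state,
        )
        tree.fit(X.to_numpy(dtype=float), y)
        self.tree_ = tree
        t = tree.tree_
        used = [i for i in range(t.node_count) if t.children_left[i] != -1]
        thresholds: dict[str, list[float]] = {}
        for node in used:
            fname = str(X.columns[t.feature[node]])
            thresholds.setdefault(fname, []).append(float(t.threshold[node]))
        order = np.argsort(tree.feature_importances_)[::-1]
        feats = [str(X.columns[i]) for i in order if tree.feature_importances_[i] > 0]
        imps = np.array(sorted(tree.feature_importances_, reverse=True))[: len(feats)]
        acc = float(tree.score(X.to_numpy(dtype=float), y))
        self.importances_ = tree.feature_importances_
        self.accuracy_ = acc
        self.report_ = AttributionReport(
            features=feats,
            importances=imps,
            split_thresholds=thresholds,
            accuracy=acc,
            n_rules=len(used),
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict(_as_frame(X).to_numpy(dtype=float))


def attribute_clusters(
    features: pd.DataFrame,
    labels: np.ndarray | ClusterAssignment,
    max_rules: int = 2,
    seed: int | None = 0,
) -> AttributionReport:
    """Fit a <= ``max_rules``-split tree and report importances and thresholds."""
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    attributor = DecisionTreeAttributor(max_rules=max_rules, random_state=seed)
    attributor.fit(features, y)
    return attributor.report_


def bootstrap_stability(
    features: pd.DataFrame,
    labels: np.ndarray | ClusterAssignment,
    n_resamples: int = 100,
    frac: float = 0.80,
    max_rules: int = 2,
    top: int = 2,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of 80 % condition resamples in which each feature splits the tree.

    Resamples are drawn without replacement; per resample the tree is refit
    and its top-``top`` split features recorded.  Returns feature ->
    fraction of resamples in which it appeared (features never selected are
    absent).  ``n_resamples = 0`` yields an empty report.
    """
    features = _as_frame(features)
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    if n_resamples == 0:
        return {}
    rng = np.random.default_rng(seed)
    n = features.shape[0]
    size = max(2, int(round(frac * n)))
    counts: dict[str, int] = {}
    done = 0
    for _ in range(n_resamples):
        idx = rng.choice(n, size=size, replace=False)
        sub_y = y[idx]
        if len(np.unique(sub_y)) < 2:
            continue
        rep = attribute_clusters(
            features.iloc[idx], sub_y, max_rules=max_rules, seed=seed
        )
        for f in rep.features[:top]:
            counts[f] = counts.get(f, 0) + 1
        done += 1
    return {f: c / done for f, c in counts.items()} if done else {}


def export_ordered_matrix(
    fused: SimilarityLayer | np.ndarray,
    labels: np.ndarray | ClusterAssignment,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permute the fused matrix to group clusters; return matrix + side table.

    Rows/columns are reordered so conditions of one cluster are contiguous
    (stable within clusters).  The side table carries the label and any
    per-condition ``annotations`` columns (e.g. a selected flux), in the
    same order.
    """
    if isinstance(fused, SimilarityLayer):
        W = fused.matrix
        node_ids = list(fused.node_ids)
    else:
        W = np.asarray(fused, dtype=float)
        node_ids = [str(i) for i in range(W.shape[0])]
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    order = np.argsort(y, kind="stable")
    ids = [node_ids[i] for i in order]
    ordered = pd.DataFrame(W[np.ix_(order, order)], index=ids, columns=ids)
    side = pd.DataFrame({"cluster": y[order]}, index=ids)
    if annotations is not None:
        ann = annotations.reindex(node_ids).iloc[order]
        side = pd.concat([side, ann], axis=1)
    return ordered, side


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[str(i) for i in range(arr.shape[1])])
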