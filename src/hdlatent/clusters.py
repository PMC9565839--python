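"""Subject clustering in factor-score space and the cluster classifier.

K-means with seeded restarts partitions subjects by their factor
scores; the cluster count is picked by the variance-ratio
(Calinski-Harabasz) criterion unless fixed.  Clusters are relabeled by
descending size (C0 largest) and clusters with fewer than 5 members are
flagged as minor (too small for group statistics).  A shallow CART
decision tree, cross-validated with stratified 3-fold splits, maps
clinical + imaging variables to the {C0, C5, other} grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClusterAssignment",
    "kmeans_factor_space",
    "representative_subject",
    "train_cluster_tree",
    "tree_to_dict",
    "tree_to_dot",
]

MINOR_CLUSTER_SIZE = 5


@dataclass
class ClusterAssignment:
    subject_id: str
    cluster_id: int
    distance_to_centroid: float
    minor_flag: bool


def kmeans_factor_space(
    scores: np.ndarray,
    subject_ids: list[str],
    n_clusters: int | str = "auto",
    seed: int = 0,
    n_restarts: int = 10,
    max_clusters: int = 10,
    criterion: str = "calinski_harabasz",
) -> tuple[list[ClusterAssignment], np.ndarray]:
    """Cluster subjects on their factor scores.

    ``n_clusters="auto"`` maximizes the chosen criterion over 2..10.
    Returns assignments (clusters relabeled by descending size) and the
    centroid matrix in the relabeled order.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if len(subject_ids) != n:
        raise ValueError("subject_ids and scores must align")
    n_unique = len(np.unique(scores, axis=0))

    def fit(k):
        return KMeans(k, n_init=n_restarts, random_state=seed).fit(scores)

    if n_clusters == "auto":
        best_k, best_val = None, -np.inf
        for k in range(2, min(max_clusters, n_unique - 1) + 1):
            labels = fit(k).labels_
            if len(np.unique(labels)) < 2:
                continue
            if criterion == "calinski_harabasz":
                val = calinski_harabasz_score(scores, labels)
            elif criterion == "silhouette":
                val = silhouette_score(scores, labels)
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            if val > best_val:
                best_k, best_val = k, val
        if best_k is None:
            raise ValueError("no cluster count produced a valid partition")
        k = best_k
    else:
        k = int(n_clusters)
        if k > n:
            raise ValueError("more clusters than subjects")
        if k > n_unique:
            raise ValueError(
                f"only {n_unique} distinct score vectors for {k} clusters"
            )
    km = fit(k)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = km.cluster_centers_[order]
    assignments = [
        ClusterAssignment(
            subject_id=sid,
            cluster_id=int(lab),
            distance_to_centroid=float(np.linalg.norm(scores[i] - centroids[lab])),
            minor_flag=bool(sizes[order][lab] < MINOR_CLUSTER_SIZE),
        )
        for i, (sid, lab) in enumerate(zip(subject_ids, labels))
    ]
    return assignments, centroids


def representative_subject(
    assignments: list[ClusterAssignment], cluster_id: int
) -> str:
    """Subject closest to the cluster centroid in factor-score space
    (ties break lexicographically on subject id)."""
    members = [a for a in assignments if a.cluster_id == cluster_id]
    if not members:
        raise ValueError(f"cluster {cluster_id} is empty")
    return min(members, key=lambda a: (a.distance_to_centroid, a.subject_id)).subject_id


def train_cluster_tree(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    max_depth: int = 3,
    seed: int = 0,
    n_folds: int = 3,
) -> tuple[DecisionTreeClassifier, float]:
    """CART (Gini) on the {C0, C5, other} grouping with stratified
    cross-validated accuracy.  ``features`` should be restricted to
    variables with significant inter-cluster differences."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs >= {n_folds} members for {n_folds}-fold stratification"
        )
    x = features.to_numpy(dtype=float)
    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = float(cross_val_score(tree, x, y, cv=cv, scoring="accuracy").mean())
    tree.fit(x, y)
    return tree, acc


def tree_to_dict(tree: DecisionTreeClassifier, feature_names: list[str]) -> dict:
    """JSON-ready nested representation (feature, threshold, class counts)."""
    t = tree.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            return {"leaf": True, "counts": t.value[i][0].tolist()}
        return {
            "leaf": False,
            "feature": feature_names[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "counts": t.value[i][0].tolist(),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return node(0)


def tree_to_dot(tree: DecisionTreeClassifier, feature_names: list[str],
                class_names: list[str]) -> str:
    from sklearn.tree import export_graphviz

    return export_graphviz(
        tree, feature_names=feature_names, class_names=class_names,
        filled=False, impurity=True,
    )
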