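"""Response-type classification by silhouette-guided k-means.

Each neuron is summarized by a two-dimensional feature: its baseline-Z-
scored mean activity 100-300 ms after onset of contralateral good and of
contralateral bad objects. Silhouette analysis over a candidate range of
cluster counts selects K, and k-means (k-means++ with multiple restarts)
assigns neurons to response types. Cluster labels are canonicalized by
centroid geometry so they carry the field's semantics regardless of
k-means' arbitrary numbering: cluster 1 = good-preferring (largest
``z_good - z_bad``), cluster 2 = bad-preferring (smallest), cluster 3 =
the remainder (visual/value-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray  # canonical labels in 1..k, per neuron
    centroids: np.ndarray  # (k, 2) in canonical order
    neuron_ids: list[str]
    silhouette_by_k: dict[int, float]
    inertia: float
    seed: int


def build_features(
    activity_table: pd.DataFrame,
    window_label: str = "target_onset",
) -> pd.DataFrame:
    """Per-neuron (z_good_contra, z_bad_contra) features.

    Expects a long-format activity table with contra rows; neurons missing
    either condition are dropped. Scene is averaged out (cells are averaged
    with equal weight).
    """
    contra = activity_table[activity_table["direction"] == "contra"]
    rows = []
    for nid, sub in contra.groupby("Neuron_ID"):
        goods = sub.loc[sub["value"] == "good", "NeuronalActivity"]
        bads = sub.loc[sub["value"] == "bad", "NeuronalActivity"]
        if goods.empty or bads.empty:
            continue
        rows.append((nid, float(goods.mean()), float(bads.mean())))
    return pd.DataFrame(rows, columns=["neuron_id", "z_good_contra", "z_bad_contra"])


def _feature_matrix(features: pd.DataFrame) -> np.ndarray:
    X = features[["z_good_contra", "z_bad_contra"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def select_k(
    features: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[int, dict[int, float]]:
    """Mean silhouette per candidate K (Euclidean); best K = argmax.

    Ties (within 1e-12) resolve to the lowest K, which also covers
    degenerate duplicate-point geometries deterministically.
    """
    X = _feature_matrix(features)
    if len(X) < max(k_range) + 1:
        raise ValueError("need at least max(k_range) + 1 neurons")
    scores: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(X, km.labels_))
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def kmeans_assign(
    features: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterResult:
    """Best-of-restarts k-means with canonical cluster numbering."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _feature_matrix(features)
    if k > len(X):
        raise ValueError("k exceeds the number of neurons")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    centroids = km.cluster_centers_
    order = _canonical_order(centroids)
    relabel = np.empty(k, dtype=int)
    for canonical, original in enumerate(order, start=1):
        relabel[original] = canonical
    labels = relabel[km.labels_]
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=centroids[order],
        neuron_ids=list(features["neuron_id"]),
        silhouette_by_k={},
        inertia=float(km.inertia_),
        seed=seed,
    )


def _canonical_order(centroids: np.ndarray) -> list[int]:
    """Canonical ordering of centroid indices by value preference.

    The centroid with the largest ``z_good - z_bad`` becomes cluster 1,
    the smallest becomes cluster 2, and the remainder follow in descending
    preference order (for k = 3 the leftover is cluster 3).
    """
    diff = centroids[:, 0] - centroids[:, 1]
    descending = list(np.argsort(-diff))
    if len(descending) < 2:
        return descending
    first, last = descending[0], descending[-1]
    middle = descending[1:-1]
    return [first, last, *middle]


def cluster_neurons(
    features: pd.DataFrame,
    k: int | str = "auto",
    seed: int = 0,
    k_range: range = range(2, 9),
    n_restarts: int = 50,
) -> ClusterResult:
    """Silhouette selection (``k='auto'``) followed by k-means assignment."""
    if k == "auto":
        k_best, scores = select_k(features, k_range=k_range, seed=seed,
                                  n_restarts=n_restarts)
    else:
        k_best, scores = int(k), {}
    result = kmeans_assign(features, k=k_best, seed=seed, n_restarts=n_restarts)
    result.silhouette_by_k = scores
    return result


def label_accuracy(result: ClusterResult, true_labels: np.ndarray) -> float:
    """Best-matching accuracy between cluster labels and generating labels,
    maximized over all label permutations (exhaustive for small k)."""
    from itertools import permutations

    true = np.asarray(true_labels)
    uniq = np.unique(true)
    best = 0.0
    for perm in permutations(range(1, result.k + 1), len(uniq)):
        mapping = dict(zip(uniq, perm))
        acc = float(np.mean([mapping[t] == l for t, l in zip(true, result.labels)]))
        best = max(best, acc)
    return best
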