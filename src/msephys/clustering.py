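"""Hierarchical classification of rhythmic medial-septal units.

Units are clustered on exactly two features — rate-change score and mean
RUN burst duration (ms) — each linearly rescaled to [-1, 1], using Ward's
minimum-variance agglomeration on Euclidean distances and a horizontal cut
leaving four clusters.  Cluster quality is the silhouette
``S_i = (b_i - a_i) / max(a_i, b_i)``, and the four clusters receive
semantic labels (Teevra, Komal, group1, group4) from their median raw
features and RUN rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .core import ValidationError

__all__ = [
    "ClusterResult",
    "rescale_features",
    "ward_cluster",
    "silhouette",
    "label_groups",
    "classify_units",
]

# (rate-change score, burst duration ms) prototypes from the four group
# medians; used only to break ambiguity in the deterministic labelling rule.
GROUP_PROTOTYPES = {
    "Teevra": (-0.05, 38.0),
    "Komal": (0.21, 57.0),
    "group1": (-0.30, 45.0),
    "group4": (0.27, 45.0),
}


def rescale_features(X: np.ndarray) -> np.ndarray:
    """Linearly map each column onto [-1, 1]: x -> 2 (x - min)/(max - min) - 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("features: expected a 2-D matrix")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    if np.any(hi - lo == 0):
        cols = np.nonzero(hi - lo == 0)[0]
        raise ValidationError(f"features: column(s) {cols.tolist()} constant, cannot rescale")
    return 2.0 * (X - lo) / (hi - lo) - 1.0


def ward_cluster(X: np.ndarray, k: int = 4):
    """Ward agglomeration on Euclidean distances, cut at ``k`` clusters.

    Returns ``(labels, Z)`` with labels in 1..k (scipy fcluster ids) and the
    scipy linkage matrix ``Z`` whose heights are the Ward merge distances.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k:
        raise ValidationError(f"ward_cluster: n={n} < k={k}")
    if n == k:
        Z = linkage(X, method="ward")
        return np.arange(1, n + 1), Z
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette S_i = (b_i - a_i) / max(a_i, b_i), in [-1, 1].

    a_i is the mean distance to the other members of the point's cluster,
    b_i the minimum over other clusters of the mean distance to their
    members.  A member of a singleton cluster gets S_i = 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("silhouette: need at least 2 clusters")
    D = cdist(X, X)
    S = np.zeros(labels.size)
    for i in range(labels.size):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            S[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        S[i] = 0.0 if denom == 0 else (b - a) / denom
    return S


def label_groups(labels, raw_features, run_rates) -> dict:
    """Semantic names for the four clusters from their median features.

    Deterministic rule: among clusters with median score > 0.1, Komal is
    the one with the longer median burst duration, group4 the other;
    group1 is the cluster with the most negative median score and the
    lowest median RUN rate; Teevra is the remaining one.  If the rule does
    not apply cleanly, clusters are matched one-to-one to the group
    prototype medians by nearest centroid in rescaled feature space.
    """
    labels = np.asarray(labels)
    raw = np.asarray(raw_features, dtype=float)
    run_rates = np.asarray(run_rates, dtype=float)
    uniq = list(np.unique(labels))
    med_score = {c: float(np.median(raw[labels == c, 0])) for c in uniq}
    med_burst = {c: float(np.median(raw[labels == c, 1])) for c in uniq}
    med_rate = {c: float(np.median(run_rates[labels == c])) for c in uniq}

    names = {}
    positive = [c for c in uniq if med_score[c] > 0.1]
    if len(uniq) == 4 and len(positive) == 2:
        komal = max(positive, key=lambda c: med_burst[c])
        g4 = next(c for c in positive if c != komal)
        rest = [c for c in uniq if c not in positive]
        g1 = min(rest, key=lambda c: med_score[c])
        if med_rate[g1] == min(med_rate[c] for c in rest):
            teevra = next(c for c in rest if c != g1)
            names = {komal: "Komal", g4: "group4", g1: "group1", teevra: "Teevra"}
    if not names:
        # ambiguity fallback: one-to-one nearest-centroid match to the
        # prototypes, in the data's rescaled feature space
        proto_names = list(GROUP_PROTOTYPES)
        protos = np.array([GROUP_PROTOTYPES[g] for g in proto_names])
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        medians = np.array([[med_score[c], med_burst[c]] for c in uniq])
        med_r = 2 * (medians - lo) / span - 1
        proto_r = 2 * (protos - lo) / span - 1
        cost = cdist(med_r, proto_r)
        rows, cols = linear_sum_assignment(cost)
        names = {uniq[i]: proto_names[j] for i, j in zip(rows, cols)}
        warnings.warn("label_groups: deterministic rule ambiguous, "
                      "used nearest-prototype matching")
    return names


@dataclass
class ClusterResult:
    """Four-way Ward classification of a unit cohort."""

    unit_ids: list
    labels: np.ndarray          # cluster ids 1..4
    linkage_tree: np.ndarray    # scipy linkage matrix
    silhouettes: np.ndarray     # per-unit S_i
    cluster_medians: dict       # cluster id -> (median score, median burst ms)
    group_names: dict           # cluster id -> semantic name

    def group_of(self, unit_id) -> str:
        i = self.unit_ids.index(unit_id)
        return self.group_names.get(self.labels[i], "")

    def mean_silhouette(self, cluster_id) -> float:
        return float(np.mean(self.silhouettes[self.labels == cluster_id]))


def classify_units(unit_ids, scores, burst_ms, run_rates, k: int = 4) -> ClusterResult:
    """Full classification: rescale -> Ward cut at 4 -> silhouette -> names."""
    raw = np.column_stack([scores, burst_ms])
    resc = rescale_features(raw)
    labels, Z = ward_cluster(resc, k=k)
    sil = silhouette(resc, labels)
    medians = {
        int(c): (float(np.median(raw[labels == c, 0])),
                 float(np.median(raw[labels == c, 1])))
        for c in np.unique(labels)
    }
    names = label_groups(labels, raw, run_rates)
    return ClusterResult(list(unit_ids), labels, Z, sil, medians,
                         {int(c): n for c, n in names.items()})
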