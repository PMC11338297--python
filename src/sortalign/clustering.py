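"""Cluster-number estimation for sorts: k-medoids (PAM) with silhouette
model selection.

A medoid is the cluster member whose average distance to the other members
is smallest.  ``pam`` is the classic deterministic BUILD + SWAP algorithm on
Euclidean pixel distances; ``estimate_k`` selects the k in a candidate range
(default 2..10) that maximizes the average silhouette width, ties broken
toward smaller k.  Silhouette of a singleton cluster is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import silhouette_score

from sortalign.simulate import SortRecord


@dataclass(frozen=True)
class ClusterResult:
    k: int
    medoid_indices: tuple[int, ...]
    assignment: tuple[int, ...]  # item index -> cluster index
    avg_silhouette: float
    total_cost: float  # sum of distances of items to their medoid


def _assign(dist: np.ndarray, medoids: Sequence[int]) -> tuple[np.ndarray, float]:
    med = np.asarray(medoids)
    d_to_med = dist[:, med]
    labels = np.argmin(d_to_med, axis=1)
    cost = float(d_to_med[np.arange(dist.shape[0]), labels].sum())
    return labels, cost


def pam_from_distances(dist: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """BUILD + SWAP k-medoids on a precomputed distance matrix.

    Deterministic: BUILD greedily adds the medoid with the largest cost
    reduction (ties to the lowest index); SWAP repeatedly applies the best
    strictly improving (medoid, non-medoid) exchange, ties broken by lowest
    indices, until no swap improves the cost.
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # BUILD: start from the most central point
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    _, cost = _assign(dist, medoids)
    # SWAP
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                _, c = _assign(dist, cand)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            cost, mi, h = best
            medoids[mi] = h
            improved = True
    medoids = sorted(medoids)
    labels, cost = _assign(dist, medoids)
    return medoids, labels, cost


def pam(points: np.ndarray | SortRecord, k: int) -> ClusterResult:
    """k-medoids clustering of item coordinates (Euclidean distances)."""
    xy = points.xy if isinstance(points, SortRecord) else np.asarray(points, dtype=float)
    n = xy.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of items n={n}")
    dist = squareform(pdist(xy))
    medoids, labels, cost = pam_from_distances(dist, k)
    if 2 <= k <= n - 1 and len(set(labels)) >= 2:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = 0.0
    return ClusterResult(
        k=k,
        medoid_indices=tuple(medoids),
        assignment=tuple(int(l) for l in labels),
        avg_silhouette=sil,
        total_cost=cost,
    )


def estimate_k(
    points: np.ndarray | SortRecord, k_range: Sequence[int] | None = None
) -> tuple[int, ClusterResult]:
    """Pick the k in ``k_range`` (default 2..10, capped at n-1) maximizing
    average silhouette width; ties go to the smaller k."""
    xy = points.xy if isinstance(points, SortRecord) else np.asarray(points, dtype=float)
    n = xy.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items to estimate a cluster count")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    best: tuple[int, ClusterResult] | None = None
    for k in k_range:
        res = pam(xy, k)
        if best is None or res.avg_silhouette > best[1].avg_silhouette + 1e-12:
            best = (k, res)
    return best


def cluster_counts(
    cohort: Sequence[SortRecord], k_range: Sequence[int] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant estimated cluster counts plus per-condition mean
    count and proportion of 2-cluster sorts."""
    rows = []
    for rec in cohort:
        k, res = estimate_k(rec, k_range)
        rows.append(
            {"participant_id": rec.participant_id, "condition": rec.condition,
             "n_clusters": k, "avg_silhouette": res.avg_silhouette}
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("condition")["n_clusters"]
        .agg(mean_clusters="mean", two_cluster_prop=lambda s: float((s == 2).mean()))
        .reset_index()
    )
    return table, summary
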