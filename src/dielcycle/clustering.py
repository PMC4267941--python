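"""Subdivision of phase clusters into expression subclusters.

Cycling genes are first grouped by peak ZT (the phase cluster, assigned in
:mod:`dielcycle.rhythm`); within each phase the min-max-normalized profiles
are partitioned by two rounds of k-means so the final subclusters fall in a
configurable size band (default 10-90 genes), suitable for downstream
promoter-motif work.  Hierarchical (average-linkage) leaf ordering is
provided for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

__all__ = [
    "normalize_profile",
    "normalize_profiles",
    "ExpressionCluster",
    "two_round_kmeans",
    "hierarchical_order",
    "subcluster_phases",
]


def normalize_profiles(rows: np.ndarray) -> np.ndarray:
    """Min-max scale each row to [0, 1]; constant rows map to all 0.5."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    lo = rows.min(axis=1, keepdims=True)
    hi = rows.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.full_like(rows, 0.5)
    ok = span[:, 0] > 0
    out[ok] = (rows[ok] - lo[ok]) / span[ok]
    return out


def normalize_profile(gene_row: np.ndarray) -> np.ndarray:
    """Min-max scale one profile; affine transforms leave the result fixed."""
    return normalize_profiles(np.asarray(gene_row)[None, :])[0]


@dataclass
class ExpressionCluster:
    """A final expression subcluster within one phase cluster."""

    members: list[str]
    centroid: np.ndarray
    phase_cluster: float | None = None
    subcluster_id: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


def _lloyd(profiles: np.ndarray, k: int, seed: int, n_restarts: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, tol=1e-6)
    return km.fit_predict(profiles)


def two_round_kmeans(
    phase_members: pd.DataFrame,
    size_bounds: tuple[int, int] = (10, 90),
    seed: int = 0,
    n_restarts: int = 10,
    target_size: int = 60,
    phase_cluster: float | None = None,
) -> list[ExpressionCluster]:
    """Partition one phase cluster's normalized profiles by 2-round k-means.

    Round 1 uses ``k = ceil(n / target_size)``; any resulting cluster above
    the upper size bound is re-clustered once with ``k = ceil(size /
    target_size)``.  Clusters below the lower bound are merged into the
    nearest surviving centroid (Euclidean distance).
    """
    lo, hi = size_bounds
    genes = list(phase_members.index)
    profiles = normalize_profiles(phase_members.to_numpy(dtype=float))
    n = len(genes)
    if n < lo:
        warnings.warn(f"only {n} members (< {lo}); returning a single cluster")
        return [
            ExpressionCluster(genes, profiles.mean(axis=0), phase_cluster, 0)
        ]

    k1 = max(1, int(np.ceil(n / target_size)))
    labels = _lloyd(profiles, min(k1, n), seed, n_restarts)

    # round 2: split oversized clusters once
    groups: list[np.ndarray] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size > hi:
            k2 = max(2, int(np.ceil(idx.size / target_size)))
            sub = _lloyd(profiles[idx], min(k2, idx.size), seed + 1, n_restarts)
            for s in np.unique(sub):
                groups.append(idx[sub == s])
        else:
            groups.append(idx)

    # merge undersized clusters into the nearest retained centroid
    keep = [g for g in groups if g.size >= lo]
    small = [g for g in groups if g.size < lo]
    if not keep:  # everything undersized: collapse to one cluster
        keep = [np.concatenate(groups)]
        small = []
    centroids = np.vstack([profiles[g].mean(axis=0) for g in keep])
    for g in small:
        c = profiles[g].mean(axis=0)
        j = int(np.argmin(((centroids - c) ** 2).sum(axis=1)))
        keep[j] = np.concatenate([keep[j], g])
        centroids[j] = profiles[keep[j]].mean(axis=0)

    clusters = []
    for i, g in enumerate(sorted(keep, key=lambda g: g.min())):
        clusters.append(
            ExpressionCluster(
                [genes[j] for j in np.sort(g)],
                profiles[g].mean(axis=0),
                phase_cluster,
                i,
            )
        )
        if g.size > hi:
            warnings.warn(
                f"cluster {i} of phase {phase_cluster} has {g.size} members "
                f"(> {hi}) after two rounds"
            )
    return clusters


def hierarchical_order(members: pd.DataFrame) -> list[str]:
    """Average-linkage display ordering of normalized profiles.

    Deterministic given input order; with fewer than three members the input
    order is returned unchanged.
    """
    genes = list(members.index)
    if len(genes) < 3:
        return genes
    profiles = normalize_profiles(members.to_numpy(dtype=float))
    link = hierarchy.linkage(pdist(profiles), method="average")
    return [genes[i] for i in hierarchy.leaves_list(link)]


def subcluster_phases(
    expression: pd.DataFrame,
    fits: pd.DataFrame,
    size_bounds: tuple[int, int] = (10, 90),
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Run two-round k-means within every phase cluster of called genes.

    Returns a table indexed by gene id with columns ``phase_cluster`` and
    ``subcluster_id``.
    """
    cycling = fits[fits["is_cycling"]]
    rows = []
    for zt, sub in cycling.groupby("phase_cluster"):
        block = expression.loc[sub.index]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clusters = two_round_kmeans(
                block, size_bounds, seed=seed, n_restarts=n_restarts,
                phase_cluster=float(zt),
            )
        for c in clusters:
            rows += [
                {"gene_id": g, "phase_cluster": float(zt), "subcluster_id": c.subcluster_id}
                for g in c.members
            ]
    return pd.DataFrame(rows).set_index("gene_id")
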