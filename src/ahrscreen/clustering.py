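"""Hierarchical clustering of fingerprints with flexible-beta linkage.

Docking-gate hits are grouped with the known binders by agglomerative
clustering on Tanimoto distances (1 − TC) using the Lance–Williams
flexible-beta update

    d(k, i∪j) = α·d(k,i) + α·d(k,j) + β·d(i,j),   α = (1−β)/2,  γ = 0,

with β = 0.25 (so α = 0.375).  Since 2α + β = 1, the linkage is monotone
and dendrogram heights never decrease — this is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .descriptors import FingerprintSet
from .similarity import tanimoto_matrix

FLEXIBLE_BETA = 0.25


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` holds (cluster_a, cluster_b, height, new_size) with cluster
    indices 0..n−1 for leaves and n+step for merged clusters, exactly n−1
    entries for n leaves, heights non-decreasing.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("dendrogram must contain exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-10 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


def tanimoto_distance_matrix(fps: FingerprintSet) -> np.ndarray:
    """Symmetric distance matrix D_ij = 1 − TC_ij with zero diagonal."""
    if len(fps.ids) < 2:
        raise ValueError("need at least 2 fingerprints")
    d = 1.0 - tanimoto_matrix(fps, fps)
    np.fill_diagonal(d, 0.0)
    return d


def flexible_beta_cluster(
    d: np.ndarray, beta: float = FLEXIBLE_BETA,
    leaf_ids: list[str] | None = None,
) -> Dendrogram:
    """Agglomerate a distance matrix with the flexible-beta recurrence.

    Merge order: minimum current inter-cluster distance; ties broken by the
    smallest (cluster index, cluster index) pair, which makes the result
    deterministic and independent of floating-point argmin order.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    if not -1.0 < beta < 1.0:
        raise ValueError("beta must be in (-1, 1)")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length does not match matrix")

    alpha = (1.0 - beta) / 2.0
    # dist maps active cluster index -> {other active index -> distance}
    dist: dict[int, dict[int, float]] = {
        i: {j: float(d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_idx = n
    last_height = 0.0
    for _ in range(n - 1):
        best = None
        for i in sorted(dist):
            for j in sorted(dist[i]):
                if j <= i:
                    continue
                cand = (dist[i][j], i, j)
                if best is None or cand < best:
                    best = cand
        height, i, j = best
        assert height >= last_height - 1e-10, "flexible-beta linkage must be monotone"
        last_height = max(last_height, height)
        d_ij = dist[i][j]
        new = {}
        for k in dist:
            if k in (i, j):
                continue
            new[k] = alpha * dist[k][i] + alpha * dist[k][j] + beta * d_ij
        size = sizes.pop(i) + sizes.pop(j)
        del dist[i], dist[j]
        for k in dist:
            dist[k].pop(i, None)
            dist[k].pop(j, None)
            dist[k][next_idx] = new[k]
        dist[next_idx] = new
        sizes[next_idx] = size
        merges.append((i, j, float(height), size))
        next_idx += 1
    return Dendrogram(list(leaf_ids), merges)


def cut(
    dendrogram: Dendrogram,
    k: int | None = None,
    height: float | None = None,
) -> dict[str, str]:
    """Cut the dendrogram into flat clusters.

    Either ``k`` (number of clusters) or ``height`` (merge heights strictly
    above it are undone) must be given.  Labels are canonical: each cluster
    is named after its lexicographically smallest member id, so the
    assignment is stable under leaf-order permutation.
    """
    n = len(dendrogram.leaf_ids)
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        n_merges = sum(1 for m in dendrogram.merges if m[2] <= height)

    members: dict[int, list[str]] = {i: [dendrogram.leaf_ids[i]] for i in range(n)}
    next_idx = n
    for a, b, _, _ in dendrogram.merges[:n_merges]:
        members[next_idx] = members.pop(a) + members.pop(b)
        next_idx += 1
    assignment: dict[str, str] = {}
    for group in members.values():
        label = min(group)
        for mol_id in group:
            assignment[mol_id] = label
    return assignment


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export: leaf names = compound ids, branch lengths = height deltas."""
    n = len(dendrogram.leaf_ids)
    node_repr: dict[int, str] = {
        i: dendrogram.leaf_ids[i] for i in range(n)
    }
    node_height: dict[int, float] = {i: 0.0 for i in range(n)}
    next_idx = n
    for a, b, h, _ in dendrogram.merges:
        la = h - node_height.pop(a)
        lb = h - node_height.pop(b)
        node_repr[next_idx] = (
            f"({node_repr.pop(a)}:{la:.6g},{node_repr.pop(b)}:{lb:.6g})"
        )
        node_height[next_idx] = h
        next_idx += 1
    root = max(node_repr)
    return node_repr[root] + ";"


def write_merge_table(path: str | Path, dendrogram: Dendrogram) -> None:
    lines = ["cluster_a\tcluster_b\theight\tnew_size"]
    lines += [f"{a}\t{b}\t{h:.10g}\t{s}" for a, b, h, s in dendrogram.merges]
    Path(path).write_text("\n".join(lines) + "\n")
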