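"""Ligand-based screening: fingerprint Tanimoto and PC-space nearest neighbors.

Two of the three parallel enrichment methods.  A candidate is a fingerprint
hit when its best Tanimoto coefficient against any reference binder reaches
0.60 (inclusive); it is a nearest-neighbor hit when it lies within Euclidean
distance 5.0 of a reference in significant-PC score space and survives the
per-reference cap of ten nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemspace import ScoreMatrix
from .descriptors import FingerprintSet

TC_CUTOFF = 0.60
ED_CUTOFF_NN = 5.0
MAX_NEIGHBORS = 10


@dataclass(frozen=True)
class SimilarityHit:
    reference_id: str
    candidate_id: str
    value: float
    kind: str  # "tanimoto" | "euclidean"


@dataclass
class NeighborList:
    """Up to ten candidates within the ED cutoff of one reference, nearest first."""

    reference_id: str
    neighbors: list[tuple[str, float]]


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient n_same / (n_a + n_b − n_same) of two key vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    n_a = int(a.sum())
    n_b = int(b.sum())
    if n_a == 0 and n_b == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    n_same = int((a & b).sum())
    return n_same / (n_a + n_b - n_same)


def tanimoto_matrix(fps_a: FingerprintSet, fps_b: FingerprintSet) -> np.ndarray:
    """All-pairs TC matrix (rows: fps_a, columns: fps_b), vectorized."""
    a = fps_a.bits.astype(np.int64)
    b = fps_b.bits.astype(np.int64)
    inter = a @ b.T
    n_a = a.sum(axis=1)[:, None]
    n_b = b.sum(axis=1)[None, :]
    denom = n_a + n_b - inter
    if np.any(denom == 0):
        raise ValueError("Tanimoto undefined for a pair of all-zero fingerprints")
    return inter / denom


def fingerprint_screen(
    references: FingerprintSet,
    candidates: FingerprintSet,
    tc_cutoff: float = TC_CUTOFF,
) -> tuple[set[str], list[SimilarityHit]]:
    """Structural-fingerprint enrichment.

    A candidate is a hit iff its maximum TC over the references is at or
    above the cutoff; the hit table records the maximizing reference (ties
    broken by reference order).
    """
    if not references.ids:
        raise ValueError("reference fingerprint set is empty")
    if not candidates.ids:
        return set(), []
    tc = tanimoto_matrix(references, candidates)
    best_ref = tc.argmax(axis=0)
    best_tc = tc.max(axis=0)
    hits: set[str] = set()
    table: list[SimilarityHit] = []
    for j, cand_id in enumerate(candidates.ids):
        if best_tc[j] >= tc_cutoff:
            hits.add(cand_id)
            table.append(SimilarityHit(references.ids[best_ref[j]], cand_id,
                                       float(best_tc[j]), "tanimoto"))
    return hits, table


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two PC-score vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("score-vector dimensionalities differ")
    return float(np.sqrt(np.sum((q - p) ** 2)))


def nearest_neighbor_screen(
    reference_scores: ScoreMatrix,
    candidate_scores: ScoreMatrix,
    ed_cutoff: float = ED_CUTOFF_NN,
    max_neighbors: int = MAX_NEIGHBORS,
) -> tuple[set[str], list[NeighborList]]:
    """Nearest-neighbor enrichment in significant-PC score space.

    Per reference, candidates within the ED cutoff (inclusive) are sorted by
    ascending distance and truncated to ``max_neighbors``; ties at the
    capacity boundary resolve by candidate-id lexicographic order so the
    output is invariant under input permutation.  The overall hit set is the
    union over references.
    """
    if reference_scores.model_tag != candidate_scores.model_tag:
        raise ValueError("score matrices come from different PCA models")
    if not reference_scores.ids:
        raise ValueError("reference score matrix is empty")
    ref = reference_scores.scores
    cand = candidate_scores.scores
    if ref.shape[1] != cand.shape[1]:
        raise ValueError("score-space dimensionalities differ")
    d = np.sqrt(((ref[:, None, :] - cand[None, :, :]) ** 2).sum(axis=2))
    hits: set[str] = set()
    lists: list[NeighborList] = []
    for i, ref_id in enumerate(reference_scores.ids):
        within = [
            (candidate_scores.ids[j], float(d[i, j]))
            for j in range(cand.shape[0])
            if d[i, j] <= ed_cutoff
        ]
        within.sort(key=lambda t: (t[1], t[0]))
        kept = within[:max_neighbors]
        hits.update(cid for cid, _ in kept)
        lists.append(NeighborList(ref_id, kept))
    return hits, lists


def write_hit_table(path: str | Path, hits: Sequence[SimilarityHit]) -> None:
    df = pd.DataFrame(
        [(h.reference_id, h.candidate_id, h.value, h.kind) for h in hits],
        columns=["reference_id", "candidate_id", "value", "method"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_neighbor_table(path: str | Path, lists: Sequence[NeighborList]) -> None:
    rows = [
        (nl.reference_id, cid, ed, "euclidean")
        for nl in lists
        for cid, ed in nl.neighbors
    ]
    pd.DataFrame(rows, columns=["reference_id", "candidate_id", "value", "method"]) \
        .to_csv(path, sep="\t", index=False)
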