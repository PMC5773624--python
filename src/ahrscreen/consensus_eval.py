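"""Consensus voting over the three parallel methods and screening evaluation.

A compound becomes a consensus hit when at least ``min_votes`` (default 2)
of the three enrichment methods — structural fingerprints, nearest-neighbor
analysis and docking-score gating — select it.  Predictions are evaluated
against active/inactive labels with accuracy, sensitivity and specificity
on an explicit evaluation universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

METHODS = ("fingerprint", "nearest_neighbor", "docking")


@dataclass(frozen=True)
class MethodHits:
    method: str
    ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "ids", frozenset(self.ids))


@dataclass
class ConsensusResult:
    votes: dict[str, int]
    min_votes: int

    @property
    def consensus_ids(self) -> set[str]:
        return {i for i, v in self.votes.items() if v >= self.min_votes}

    @property
    def triple_ids(self) -> set[str]:
        return {i for i, v in self.votes.items() if v == len(METHODS)}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity, specificity; ``None`` marks an undefined metric."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def rounded(self, ndigits: int = 2) -> "Metrics":
        def r(x: Optional[float]) -> Optional[float]:
            if x is None:
                return None
            # half-up rounding, as printed in screening summaries
            scale = 10 ** ndigits
            return int(x * scale + 0.5) / scale

        return Metrics(r(self.accuracy), r(self.sensitivity), r(self.specificity))


def consensus(hits: Sequence[MethodHits], min_votes: int = 2) -> ConsensusResult:
    """Count per-compound votes across the three methods."""
    methods = [h.method for h in hits]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate method labels in consensus input")
    if len(hits) != len(METHODS):
        raise ValueError(f"consensus expects {len(METHODS)} method hit sets")
    votes: dict[str, int] = {}
    for h in hits:
        for mol_id in h.ids:
            votes[mol_id] = votes.get(mol_id, 0) + 1
    return ConsensusResult(votes, min_votes)


def confusion(
    predicted: set[str],
    labels: Mapping[str, str],
) -> ConfusionCounts:
    """Confusion counts of a predicted hit set against active/inactive labels.

    The evaluation universe is the labeled set; predicted ids outside it are
    ignored (their count is logged).  Ambiguous labels must be excluded
    upstream.
    """
    bad = {v for v in labels.values() if v not in ("active", "inactive")}
    if bad:
        raise ValueError(f"labels must be active/inactive, got {sorted(bad)}")
    if not labels:
        raise ValueError("empty evaluation universe")
    outside = {i for i in predicted if i not in labels}
    if outside:
        logger.info("%d predicted ids outside the evaluation universe", len(outside))
    active = {i for i, lbl in labels.items() if lbl == "active"}
    inactive = set(labels) - active
    pred = predicted & set(labels)
    return ConfusionCounts(
        tp=len(pred & active),
        fp=len(pred & inactive),
        tn=len(inactive - pred),
        fn=len(active - pred),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity; zero denominators yield ``None``."""
    total = counts.tp + counts.fp + counts.tn + counts.fn
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    return Metrics(
        accuracy=(counts.tp + counts.tn) / total if total else None,
        sensitivity=counts.tp / pos if pos else None,
        specificity=counts.tn / neg if neg else None,
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_id_file(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def read_label_table(path: str | Path, drop_ambiguous: bool = True) -> dict[str, str]:
    """Read a tab-separated id/label table, dropping ambiguous labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "activity"}.issubset(df.columns):
        raise ValueError("label table needs 'id' and 'activity' columns")
    labels = dict(zip(df["id"], df["activity"]))
    if drop_ambiguous:
        labels = {i: v for i, v in labels.items() if v in ("active", "inactive")}
    return labels


def write_votes_table(path: str | Path, result: ConsensusResult) -> None:
    lines = ["id\tvotes\tconsensus"]
    for mol_id in sorted(result.votes):
        v = result.votes[mol_id]
        lines.append(f"{mol_id}\t{v}\t{int(v >= result.min_votes)}")
    Path(path).write_text("\n".join(lines) + "\n")
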