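"""Docking-score gating: best-pose selection and the reference-based cutoff.

The structure-based enrichment consumes externally produced binding free
energies (ΔG_bind, kcal/mol, more negative = stronger predicted binding);
the docking engine itself sits behind a plain score-table contract, so any
engine — or the synthetic generator — can feed it.  Per compound the best
(lowest) ΔG_bind over all stereoisomers and poses is kept; the gate passes
candidates whose best ΔG_bind is within one sample standard deviation above
the reference binders' mean (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DockScoreRecord:
    compound_id: str
    stereoisomer_id: str
    pose_rank: int
    dg_bind: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")
        if not np.isfinite(self.dg_bind):
            raise ValueError("dg_bind must be finite")


@dataclass(frozen=True)
class ReferenceStats:
    """Mean/SD of the reference binders' best-pose ΔG_bind and the gate cutoff."""

    n: int
    mean_dg: float
    sd_dg: float

    @property
    def cutoff(self) -> float:
        return self.mean_dg + self.sd_dg


@dataclass
class BestPoseTable:
    """Per-compound minimum ΔG_bind with the winning stereoisomer/pose."""

    dg: dict[str, float]
    winner: dict[str, tuple[str, int]]
    failed: list[str]


def best_pose_per_compound(
    records: Sequence[DockScoreRecord],
    expected_ids: Iterable[str] | None = None,
) -> BestPoseTable:
    """Select the lowest ΔG_bind per compound over stereoisomers and poses.

    Ties resolve to the lexicographically smallest (stereoisomer_id,
    pose_rank).  Compounds in ``expected_ids`` with no score records are
    listed as failed in docking and excluded downstream.
    """
    seen = {(r.compound_id, r.stereoisomer_id, r.pose_rank) for r in records}
    if len(seen) != len(records):
        raise ValueError("duplicate (compound, stereoisomer, pose_rank) records")
    dg: dict[str, float] = {}
    winner: dict[str, tuple[str, int]] = {}
    for r in sorted(records, key=lambda r: (r.compound_id, r.stereoisomer_id,
                                            r.pose_rank)):
        best = dg.get(r.compound_id)
        if best is None or r.dg_bind < best:
            dg[r.compound_id] = r.dg_bind
            winner[r.compound_id] = (r.stereoisomer_id, r.pose_rank)
    failed = sorted(set(expected_ids) - dg.keys()) if expected_ids is not None else []
    return BestPoseTable(dg, winner, failed)


def reference_cutoff(reference_dgs: Sequence[float]) -> ReferenceStats:
    """Mean, sample SD (n−1) and mean-plus-one-SD cutoff of reference scores."""
    if len(reference_dgs) < 2:
        raise ValueError("need at least 2 reference scores")
    arr = np.asarray(reference_dgs, dtype=float)
    return ReferenceStats(n=len(arr), mean_dg=float(arr.mean()),
                          sd_dg=float(arr.std(ddof=1)))


def gate(candidate_dgs: dict[str, float], stats: ReferenceStats) -> set[str]:
    """Candidates whose best ΔG_bind is at or below the cutoff."""
    return {cid for cid, dg in candidate_dgs.items() if dg <= stats.cutoff}


# ---------------------------------------------------------------------------
# score-table I/O

SCORE_COLUMNS = ["compound_id", "stereoisomer_id", "pose_rank", "dg_bind_kcal_mol"]


def read_score_table(path: str | Path) -> list[DockScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str,
                                            "stereoisomer_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    return [
        DockScoreRecord(row.compound_id, row.stereoisomer_id,
                        int(row.pose_rank), float(row.dg_bind_kcal_mol))
        for row in df.itertuples()
    ]


def write_score_table(path: str | Path, records: Sequence[DockScoreRecord]) -> None:
    pd.DataFrame(
        [(r.compound_id, r.stereoisomer_id, r.pose_rank, r.dg_bind) for r in records],
        columns=SCORE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
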