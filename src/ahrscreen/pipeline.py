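"""End-to-end orchestration of the consensus virtual-screening protocol.

Stage order: standardize the libraries → compute 2D descriptors and
fingerprints → dual initial filtration (binder-AD "typical" branch and
log-space ED ≤ 1.5 "atypical" branch) → three parallel enrichments on the
filtration survivors (fingerprint TC ≥ 0.60; nearest neighbors at ED ≤ 5.0,
max 10 per reference; docking-score gate at the reference mean-plus-one-SD
cutoff) → ≥2-of-3 consensus voting → flexible-beta clustering of the
docking hits with the binders → evaluation against activity labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import chemspace, clustering, docking_gate, similarity
from . import consensus_eval as consensus_mod
from .descriptors import DescriptorMatrix, compute_2d_descriptors, compute_fingerprints
from .docking_gate import DockScoreRecord
from .molprep import MoleculeRecord, StandardizationReport, standardize_library
from .synthetic import CandidateLibrary, GeneratorConfig, make_activity_labels, \
    make_candidate_library, make_dock_scores, make_reference_binders

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the screening run produced, stage by stage."""

    report: StandardizationReport
    filtration: chemspace.FiltrationResult
    fingerprint_hits: set[str]
    nn_hits: set[str]
    docking_hits: set[str]
    consensus_result: consensus_mod.ConsensusResult
    metrics: Optional[consensus_mod.Metrics]
    confusion: Optional[consensus_mod.ConfusionCounts]
    cluster_assignment: dict[str, str]
    dock_stats: docking_gate.ReferenceStats

    @property
    def consensus_ids(self) -> set[str]:
        return self.consensus_result.consensus_ids

    def stage_counts(self) -> dict[str, int]:
        return {
            "standardized": self.report.n_output,
            "filtration_typical": len(self.filtration.typical_hits),
            "filtration_atypical": len(self.filtration.atypical_hits),
            "filtration_union": len(self.filtration.union),
            "fingerprint_hits": len(self.fingerprint_hits),
            "nn_hits": len(self.nn_hits),
            "docking_hits": len(self.docking_hits),
            "consensus": len(self.consensus_ids),
            "triple": len(self.consensus_result.triple_ids),
        }


def run_screen(
    binders: Sequence[MoleculeRecord],
    atypical_refs: Sequence[MoleculeRecord],
    candidates: Sequence[MoleculeRecord],
    dock_records: Sequence[DockScoreRecord],
    labels: Optional[dict[str, str]] = None,
    tc_cutoff: float = similarity.TC_CUTOFF,
    ed_cutoff_nn: float = similarity.ED_CUTOFF_NN,
    ed_cutoff_atypical: float = chemspace.ED_CUTOFF_ATYPICAL,
    max_neighbors: int = similarity.MAX_NEIGHBORS,
    min_votes: int = 2,
    cluster_k: Optional[int] = None,
) -> PipelineResult:
    """Run the full protocol on explicit libraries and a docking-score table.

    ``labels`` (id → active/inactive), when given, are evaluated on the
    universe of labeled filtration survivors.
    """
    all_refs = list(binders) + list(atypical_refs)
    std_refs, _ = standardize_library(all_refs)
    std_binders = [r for r in std_refs]
    std_atypical = [r for r in std_refs if r.id in {a.id for a in atypical_refs}]
    std_cands, report = standardize_library(candidates)
    logger.info("standardized %d/%d candidates", report.n_output, report.n_input)

    binder_desc = compute_2d_descriptors(std_binders)
    atypical_desc = compute_2d_descriptors(std_atypical)
    cand_desc = compute_2d_descriptors(std_cands)

    filtration = chemspace.initial_filtration(
        binder_desc, atypical_desc, cand_desc, ed_cutoff_atypical)
    survivors = sorted(filtration.union)
    survivor_recs = [r for r in std_cands if r.id in filtration.union]

    # method 1: structural fingerprints
    ref_fps = compute_fingerprints(std_binders)
    cand_fps = compute_fingerprints(survivor_recs)
    if survivor_recs:
        fp_hits, _ = similarity.fingerprint_screen(ref_fps, cand_fps, tc_cutoff)
    else:
        fp_hits = set()

    # method 2: nearest neighbors in the joint PC space (raw descriptors)
    nn_hits: set[str] = set()
    if survivor_recs:
        joint = DescriptorMatrix(
            list(binder_desc.ids) + [r.id for r in survivor_recs],
            list(binder_desc.names),
            np.vstack([binder_desc.values, cand_desc.subset(survivors).values]),
        )
        nn_model = chemspace.fit_pca(joint, scaling="unit_variance")
        scores = chemspace.project(nn_model, joint)
        n_ref = len(binder_desc.ids)
        ref_scores = chemspace.ScoreMatrix(
            scores.ids[:n_ref], scores.scores[:n_ref], scores.model_tag)
        cand_scores = chemspace.ScoreMatrix(
            scores.ids[n_ref:], scores.scores[n_ref:], scores.model_tag)
        nn_hits, _ = similarity.nearest_neighbor_screen(
            ref_scores, cand_scores, ed_cutoff_nn, max_neighbors)

    # method 3: docking-score gate
    binder_ids = [r.id for r in std_binders]
    best = docking_gate.best_pose_per_compound(
        dock_records, expected_ids=binder_ids + survivors)
    ref_dgs = [best.dg[i] for i in binder_ids if i in best.dg]
    stats = docking_gate.reference_cutoff(ref_dgs)
    cand_dgs = {i: best.dg[i] for i in survivors if i in best.dg}
    dock_hits = docking_gate.gate(cand_dgs, stats)

    result = consensus_mod.consensus(
        [
            consensus_mod.MethodHits("fingerprint", frozenset(fp_hits)),
            consensus_mod.MethodHits("nearest_neighbor", frozenset(nn_hits)),
            consensus_mod.MethodHits("docking", frozenset(dock_hits)),
        ],
        min_votes=min_votes,
    )

    # group docking hits with the known binders by fingerprint clustering
    cluster_assignment: dict[str, str] = {}
    cluster_members = sorted(dock_hits) + binder_ids
    if len(cluster_members) >= 2:
        member_fps = compute_fingerprints(
            [r for r in survivor_recs if r.id in dock_hits] + std_binders)
        dmat = clustering.tanimoto_distance_matrix(member_fps)
        dendro = clustering.flexible_beta_cluster(dmat, leaf_ids=member_fps.ids)
        k = cluster_k if cluster_k is not None else min(35, len(cluster_members))
        cluster_assignment = clustering.cut(dendro, k=k)

    m = conf = None
    if labels:
        universe = {i: lbl for i, lbl in labels.items()
                    if i in filtration.union and lbl in ("active", "inactive")}
        if universe:
            conf = consensus_mod.confusion(result.consensus_ids, universe)
            m = consensus_mod.metrics(conf)

    return PipelineResult(
        report=report,
        filtration=filtration,
        fingerprint_hits=fp_hits,
        nn_hits=nn_hits,
        docking_hits=dock_hits,
        consensus_result=result,
        metrics=m,
        confusion=conf,
        cluster_assignment=cluster_assignment,
        dock_stats=stats,
    )


@dataclass
class SyntheticRun:
    """A pipeline run on generated data, with ground truth kept alongside."""

    result: PipelineResult
    library: CandidateLibrary
    labels: dict[str, str]

    @property
    def precision(self) -> float:
        pred = self.result.consensus_ids
        if not pred:
            return float("nan")
        return len(pred & self.library.should_hit_ids) / len(pred)

    @property
    def recall(self) -> float:
        truth = self.library.should_hit_ids
        if not truth:
            return float("nan")
        return len(self.result.consensus_ids & truth) / len(truth)


def run_synthetic_screen(config: GeneratorConfig, **kwargs) -> SyntheticRun:
    """Generate a synthetic campaign from one seed and screen it end-to-end."""
    typical, atypical = make_reference_binders(config)
    library = make_candidate_library(config, list(typical) + list(atypical))
    ids_tags = [(r.id, "binder") for r in typical + atypical]
    ids_tags += [(r.id, library.tags[r.id]) for r in library.records]
    dock_records = make_dock_scores(config, ids_tags)
    labels = make_activity_labels(config, library.tags)
    result = run_screen(typical, atypical, library.records, dock_records,
                        labels=labels, **kwargs)
    return SyntheticRun(result, library, labels)
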