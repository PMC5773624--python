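"""Seeded synthetic inputs with the statistical structure the protocol assumes.

The generator produces, from one integer seed, everything the pipeline
consumes: a reference set of typical (rigid halogenated-aromatic /
fused-polycyclic) and atypical (flexible heteroaromatic) binders, a diverse
candidate library containing planted single-edit analogs of the references
("should-hit" ground truth), aliphatic/small-polar decoys ("should-miss"),
a small quota of excluded-element decoys to exercise curation, Gaussian
docking-score tables anchored at the reference mean of −112.5 kcal/mol, and
noisy binary activity labels.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from . import scaffolds
from .docking_gate import DockScoreRecord
from .molprep import MoleculeRecord

GROUND_TRUTH_TAGS = ("planted", "decoy", "excluded")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic screening campaign.

    Docking-score anchors follow the reference-binder distribution
    (mean −112.5, SD 13.2 kcal/mol); decoy scores (−70 ± 15) are a
    documented artifact choice giving clear but overlapping separation.
    """

    seed: int = 0
    n_candidates: int = 1000
    n_typical_refs: int = 61
    n_atypical_refs: int = 5
    n_planted_analogs: int = 60
    n_excluded_decoys: int = 10
    binder_score_mean: float = -112.5
    binder_score_sd: float = 13.2
    decoy_score_mean: float = -70.0
    decoy_score_sd: float = 15.0
    active_fraction_planted: float = 0.8
    active_fraction_decoy: float = 0.1

    def __post_init__(self) -> None:
        counts = (self.n_candidates, self.n_typical_refs, self.n_atypical_refs,
                  self.n_planted_analogs, self.n_excluded_decoys)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        fracs = (self.active_fraction_planted, self.active_fraction_decoy)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("active fractions must lie in [0, 1]")
        if self.n_planted_analogs + self.n_excluded_decoys > self.n_candidates:
            raise ValueError("planted + excluded decoys exceed n_candidates")


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _aromatic_ch_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _add_substituent(smiles: str, symbol: str, rng: np.random.Generator) -> str | None:
    """Attach one substituent atom at a random aromatic CH position."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    positions = _aromatic_ch_positions(mol)
    if not positions:
        return None
    pos = int(rng.choice(positions))
    rw = Chem.RWMol(mol)
    new_idx = rw.AddAtom(Chem.Atom(symbol))
    rw.AddBond(pos, new_idx, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def make_reference_binders(
    config: GeneratorConfig,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Generate (typical, atypical) reference binders.

    Typical binders are halogen-substituted rigid aromatic scaffolds;
    atypical binders are flexible heteroaromatic templates (optionally
    methyl/halogen decorated to reach the requested count).  Every record
    carries a potency at or below 10 µM, so all pass the binder rule.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()

    typical: list[MoleculeRecord] = []
    attempts = 0
    while len(typical) < config.n_typical_refs:
        attempts += 1
        if attempts > 200 * max(config.n_typical_refs, 1):
            raise RuntimeError("could not generate enough distinct typical binders")
        smiles = str(rng.choice(scaffolds.TYPICAL_SCAFFOLDS))
        n_halo = int(rng.integers(0, 6))
        for _ in range(n_halo):
            sym = "Cl" if rng.random() < 0.8 else "Br"
            new = _add_substituent(smiles, sym, rng)
            if new is not None:
                smiles = new
        can = _canonical(smiles)
        if can is None or can in seen:
            continue
        seen.add(can)
        potency = float(10 ** rng.uniform(-3, 1))  # 0.001–10 µM
        typical.append(MoleculeRecord(
            id=f"ref_typ_{len(typical):03d}", smiles=can, role="binder",
            potency_um=potency, name="synthetic typical binder"))

    atypical: list[MoleculeRecord] = []
    attempts = 0
    while len(atypical) < config.n_atypical_refs:
        attempts += 1
        if attempts > 200 * max(config.n_atypical_refs, 1):
            raise RuntimeError("could not generate enough distinct atypical binders")
        base = scaffolds.ATYPICAL_TEMPLATES[
            len(atypical) % len(scaffolds.ATYPICAL_TEMPLATES)]
        smiles = base
        if len(atypical) >= len(scaffolds.ATYPICAL_TEMPLATES):
            new = _add_substituent(base, str(rng.choice(["C", "Cl", "F"])), rng)
            if new is None:
                continue
            smiles = new
        can = _canonical(smiles)
        if can is None or can in seen:
            continue
        seen.add(can)
        potency = float(10 ** rng.uniform(-2, 1))
        atypical.append(MoleculeRecord(
            id=f"ref_aty_{len(atypical):02d}", smiles=can, role="binder",
            potency_um=potency, name="synthetic atypical binder"))

    return typical, atypical


def _make_decoy(rng: np.random.Generator) -> str | None:
    """One should-miss decoy.

    Three off-scaffold flavors: aliphatic chains with branches and a polar
    terminal group (~60%), ring-capped aliphatics (~15%), and single-ring
    aromatics with small substituents (~25%) that may survive the property
    filtration but remain structurally unrelated to the reference
    chemotypes.
    """
    if rng.random() < 0.25:
        core = str(rng.choice(scaffolds.DECOY_AROMATIC_CORES))
        grp = str(rng.choice(scaffolds.DECOY_AROMATIC_GROUPS))
        smiles = _canonical(core + grp)  # append one group at the ring closure
        if smiles is None:
            return None
        for _ in range(int(rng.integers(0, 2))):
            new = _add_substituent(smiles, str(rng.choice(["C", "O", "N", "F", "Cl"])),
                                   rng)
            if new is not None:
                smiles = new
        return _canonical(smiles)
    n = int(rng.integers(2, 13))
    chain = "C" * n
    if n >= 4 and rng.random() < 0.5:
        k = int(rng.integers(1, n - 2))
        chain = chain[:k] + "C(C)" + chain[k:]
    group = str(rng.choice(scaffolds.DECOY_GROUPS))
    ring = str(rng.choice(scaffolds.DECOY_RINGS)) if rng.random() < 0.25 else ""
    return _canonical(chain + group + ring)


@dataclass
class CandidateLibrary:
    """Candidate records plus hidden ground truth for calibration tests."""

    records: list[MoleculeRecord]
    tags: dict[str, str]                      # id -> planted | decoy | excluded
    planted_parent: dict[str, str] = field(default_factory=dict)

    @property
    def should_hit_ids(self) -> set[str]:
        return {i for i, t in self.tags.items() if t == "planted"}


def make_candidate_library(
    config: GeneratorConfig,
    references: Sequence[MoleculeRecord] | None = None,
) -> CandidateLibrary:
    """Generate the candidate library with hidden ground-truth tags.

    Planted analogs are single-substituent edits (Cl/Br/F/methyl at an
    aromatic CH) of reference structures; decoys are random aliphatic /
    small-polar molecules; a small quota of excluded-element decoys
    exercises the curation filter.  All three groups are shuffled into one
    deterministic id order.
    """
    if references is None:
        typical, atypical = make_reference_binders(config)
        references = list(typical) + list(atypical)
    if not references and config.n_planted_analogs:
        raise ValueError("need references to plant analogs")
    rng = np.random.default_rng(config.seed + 1)
    ref_smiles = {_canonical(r.smiles) for r in references}

    entries: list[tuple[str, str, str]] = []  # (smiles, tag, parent)
    seen: set[str] = set(ref_smiles)

    attempts = 0
    while sum(t == "planted" for _, t, _ in entries) < config.n_planted_analogs:
        attempts += 1
        if attempts > 500 * max(config.n_planted_analogs, 1):
            raise RuntimeError("could not generate enough distinct planted analogs")
        parent = references[int(rng.integers(0, len(references)))]
        sym = str(rng.choice(["Cl", "Cl", "Br", "F", "C"]))
        edited = _add_substituent(parent.smiles, sym, rng)
        if edited is None or edited in seen:
            continue
        seen.add(edited)
        entries.append((edited, "planted", parent.id))

    for smiles in scaffolds.EXCLUDED_ELEMENT_DECOYS[: config.n_excluded_decoys]:
        can = _canonical(smiles)
        if can is not None and can not in seen:
            seen.add(can)
            entries.append((can, "excluded", ""))

    n_decoys = config.n_candidates - len(entries)
    attempts = 0
    while sum(t == "decoy" for _, t, _ in entries) < n_decoys:
        attempts += 1
        if attempts > 500 * max(n_decoys, 1):
            raise RuntimeError("could not generate enough distinct decoys")
        can = _make_decoy(rng)
        if can is None or can in seen:
            continue
        seen.add(can)
        entries.append((can, "decoy", ""))

    order = rng.permutation(len(entries))
    records, tags, parents = [], {}, {}
    for new_i, old_i in enumerate(order):
        smiles, tag, parent = entries[int(old_i)]
        mol_id = f"cand_{new_i:05d}"
        records.append(MoleculeRecord(id=mol_id, smiles=smiles, role="candidate"))
        tags[mol_id] = tag
        if tag == "planted":
            parents[mol_id] = parent
    return CandidateLibrary(records, tags, parents)


def make_dock_scores(
    config: GeneratorConfig,
    ids_and_tags: Sequence[tuple[str, str]],
) -> list[DockScoreRecord]:
    """Gaussian docking-score table for the given (id, tag) sequence.

    Tags ``binder`` and ``planted`` draw the compound-level base score from
    Normal(binder_score_mean, binder_score_sd); anything else from the decoy
    distribution.  Each compound gets one or two stereoisomers with ten
    poses each; pose scores are the base plus a non-negative jitter whose
    minimum is zero, so the best pose reproduces the base draw exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    records: list[DockScoreRecord] = []
    for mol_id, tag in ids_and_tags:
        if tag in ("binder", "planted"):
            base = rng.normal(config.binder_score_mean, config.binder_score_sd)
        else:
            base = rng.normal(config.decoy_score_mean, config.decoy_score_sd)
        n_stereo = 1 + int(rng.random() < 0.3)
        for s in range(n_stereo):
            stereo_base = base if s == 0 else base + float(rng.uniform(0.5, 5.0))
            jitters = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 12.0, 9))])
            for rank, jit in enumerate(jitters, start=1):
                records.append(DockScoreRecord(
                    compound_id=mol_id, stereoisomer_id=f"iso{s + 1}",
                    pose_rank=rank, dg_bind=float(stereo_base + jit)))
    return records


def make_activity_labels(
    config: GeneratorConfig,
    tags: dict[str, str],
) -> dict[str, str]:
    """Noisy binary labels: planted compounds are active with probability
    ``active_fraction_planted``, decoys with ``active_fraction_decoy``."""
    rng = np.random.default_rng(config.seed + 3)
    labels: dict[str, str] = {}
    for mol_id in sorted(tags):
        frac = (config.active_fraction_planted if tags[mol_id] == "planted"
                else config.active_fraction_decoy)
        labels[mol_id] = "active" if rng.random() < frac else "inactive"
    return labels
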