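"""Library curation: parsing, standardization, deduplication and binder rules.

Chemical libraries arrive as SMILES or SDF files with CAS-style identifiers.
Before any descriptor or fingerprint is computed the structures are
standardized: counter ions are stripped (largest carbon-containing fragment
kept), strong acids are deprotonated, strong bases are protonated, compounds
containing elements outside the screening domain are removed, and exact
duplicates under canonical SMILES are collapsed.  Reference binders are
defined by competitive-binding potency at or below 10 µM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.error")  # parse failures are reported explicitly

#: Elements excluded from the screening library (no usable force-field /
#: descriptor parameterization for these in the original protocol).
DEFAULT_EXCLUDED_ELEMENTS = frozenset(
    {"Al", "As", "Ba", "Bi", "Cd", "Co", "Cr", "Mn", "Ni", "Pb", "Sb", "Sn",
     "Sr", "Ti", "Zr"}
)

#: Competitive-binding potency threshold (µM) defining a reference binder.
BINDER_POTENCY_UM = 10.0

ROLES = ("candidate", "binder", "modulator")


@dataclass(frozen=True)
class MoleculeRecord:
    """One chemical: identifier, structure and screening metadata.

    Parameters
    ----------
    id : str
        CAS-style identifier, unique within a library after standardization.
    smiles : str
        Structure as SMILES (canonicalized during standardization).
    name : str
        Free-text name.
    role : str
        One of ``candidate``, ``binder``, ``modulator``.
    potency_um : float, optional
        Lowest reported IC50/Ki/Kd in µM; must be positive when present.
    activity : str, optional
        ``active`` / ``inactive`` / ``ambiguous`` reporter-assay label.
    """

    id: str
    smiles: str
    name: str = ""
    role: str = "candidate"
    potency_um: Optional[float] = None
    activity: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("MoleculeRecord.id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.potency_um is not None and not self.potency_um > 0:
            raise ValueError("potency_um must be > 0 when present")
        if self.activity not in (None, "active", "inactive", "ambiguous"):
            raise ValueError(f"unknown activity label {self.activity!r}")

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparseable SMILES for {self.id}: {self.smiles!r}")
        return m


@dataclass
class StandardizationReport:
    """Bookkeeping for one standardization run.

    Every input record ends up either in the output or in ``removed_ids``
    with exactly one reason code (``parse_error``, ``excluded_element``,
    ``duplicate``).
    """

    n_input: int = 0
    n_removed_elements: int = 0
    n_removed_duplicates: int = 0
    n_removed_parse: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return (self.n_input - self.n_removed_elements
                - self.n_removed_duplicates - self.n_removed_parse)


# SMARTS for the ionization policy.  "Strong acid/base" is operationalized as
# a fixed transformation list: carboxylic, sulfonic and phosphonic acid OH
# groups are deprotonated; aliphatic amines, amidines and guanidines are
# protonated.  Applied after salt stripping so counter ions never ionize.
_ACID_PATTERNS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=O)[OX2H1]",          # carboxylic acid
        "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid
        "[PX4](=O)[OX2H1]",          # phosphonic/phosphoric acid OH
    )
]
_BASE_PATTERNS = [
    # aliphatic amine: trivalent neutral N, no aromatic/acyl/sulfonyl
    # neighbor, not double-bonded
    Chem.MolFromSmarts(
        "[NX3;H2,H1,H0;+0;!$([N]-a);!$([N]-[C,S,P]=[O,S,N]);!$([N]=*);!$([N]-[N,O])]"
    ),
    # amidine / guanidine sp2 nitrogen
    Chem.MolFromSmarts("[NX2;+0]=[CX3]([NX3])"),
]


def _deprotonate_acids(mol: Chem.RWMol) -> None:
    for patt in _ACID_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            o = mol.GetAtomWithIdx(match[-1])
            if o.GetFormalCharge() == 0 and o.GetTotalNumHs() >= 1:
                o.SetFormalCharge(-1)
                o.SetNumExplicitHs(0)
                o.SetNoImplicit(True)


def _protonate_bases(mol: Chem.RWMol) -> None:
    for patt in _BASE_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            n = mol.GetAtomWithIdx(match[0])
            if n.GetFormalCharge() == 0:
                n.SetFormalCharge(1)
                n.SetNumExplicitHs(n.GetTotalNumHs() + 1)
                n.SetNoImplicit(True)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment containing carbon.

    Ties broken by heavy-atom count then canonical-SMILES order; if no
    fragment contains carbon the largest fragment overall is kept.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    def has_carbon(m: Chem.Mol) -> bool:
        return any(a.GetAtomicNum() == 6 for a in m.GetAtoms())

    pool = [f for f in frags if has_carbon(f)] or list(frags)
    return max(pool, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))


def standardize_molecule(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a single parsed molecule (salt strip then ionize)."""
    mol = _largest_organic_fragment(mol)
    rw = Chem.RWMol(mol)
    _deprotonate_acids(rw)
    _protonate_bases(rw)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def contains_excluded_element(mol: Chem.Mol,
                              excluded: frozenset[str] | set[str]) -> bool:
    return any(a.GetSymbol() in excluded for a in mol.GetAtoms())


def standardize_library(
    records: Sequence[MoleculeRecord],
    excluded_elements: Iterable[str] = DEFAULT_EXCLUDED_ELEMENTS,
) -> tuple[list[MoleculeRecord], StandardizationReport]:
    """Standardize a library and report every removal.

    The element filter is applied to the molecule as parsed (before salt
    stripping): a compound supplied with an excluded-element counter ion is
    removed, matching the whole-compound exclusion rule.  Duplicates are
    detected by canonical SMILES of the standardized structure (stereo
    retained); the first occurrence in input order survives.
    """
    excluded = frozenset(excluded_elements)
    report = StandardizationReport(n_input=len(records))
    seen: dict[str, str] = {}  # canonical smiles -> surviving id
    out: list[MoleculeRecord] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            report.n_removed_parse += 1
            report.removed_ids.append((rec.id, "parse_error"))
            logger.warning("parse error for %s", rec.id)
            continue
        if contains_excluded_element(mol, excluded):
            report.n_removed_elements += 1
            report.removed_ids.append((rec.id, "excluded_element"))
            continue
        std = standardize_molecule(mol)
        can = Chem.MolToSmiles(std)
        if can in seen:
            report.n_removed_duplicates += 1
            report.removed_ids.append((rec.id, "duplicate"))
            continue
        seen[can] = rec.id
        out.append(replace(rec, smiles=can))
    return out, report


def classify_binder(potency_um: Optional[float]) -> Optional[bool]:
    """Binder rule: potency at or below 10 µM (boundary inclusive).

    Returns ``None`` ("unknown") when potency is missing; such records are
    excluded from the binder reference set.
    """
    if potency_um is None:
        return None
    if not potency_um > 0:
        raise ValueError("potency_um must be > 0")
    return potency_um <= BINDER_POTENCY_UM


def lowest_potency(values: Iterable[float]) -> Optional[float]:
    """Aggregate multi-assay potencies by taking the most potent (minimum)."""
    vals = [v for v in values if v is not None]
    return min(vals) if vals else None


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str | Path, role: str = "candidate") -> list[MoleculeRecord]:
    """Read a SMILES file: one record per line, ``SMILES<ws>id [name...]``."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        if len(parts) < 2:
            raise ValueError(f"malformed SMILES line (need SMILES and id): {line!r}")
        smiles, mol_id = parts[0], parts[1]
        name = parts[2] if len(parts) == 3 else ""
        records.append(MoleculeRecord(id=mol_id, smiles=smiles, name=name, role=role))
    return records


def write_smiles_file(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    lines = [f"{r.smiles}\t{r.id}" + (f"\t{r.name}" if r.name else "")
             for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sdf(path: str | Path, id_property: str = "_Name",
             role: str = "candidate") -> list[MoleculeRecord]:
    """Read an SDF; the identifier comes from a named property or title line."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(MoleculeRecord(id=f"sdf_record_{i}", smiles="<unparseable>",
                                          role=role))
            continue
        if id_property == "_Name":
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_record_{i}"
        else:
            mol_id = mol.GetProp(id_property) if mol.HasProp(id_property) else f"sdf_record_{i}"
        records.append(MoleculeRecord(id=mol_id or f"sdf_record_{i}",
                                      smiles=Chem.MolToSmiles(mol), role=role))
    return records


def write_report(path: str | Path, report: StandardizationReport) -> None:
    """Write the removal report as a tab-separated table."""
    lines = ["id\treason"]
    lines += [f"{mol_id}\t{reason}" for mol_id, reason in report.removed_ids]
    Path(path).write_text("\n".join(lines) + "\n")
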