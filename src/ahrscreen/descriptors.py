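"""2D molecular descriptors and 166-key structural fingerprints.

The screening characterizes every compound by a matrix of ~68 real-valued 2D
descriptors covering hydrophobicity (logP), polarizability/polarity
(partial-charge surface-area bins), reactivity proxies, aromaticity, size,
flexibility and shape (Balaban J, Kier kappa indices), and by the public
166-key MACCS-style structural fingerprint used for Tanimoto similarity.

The descriptor registry reproduces every descriptor family named in the
protocol and is padded with standard 2D descriptors to 68 columns; it is a
plain name → callable mapping, so users can substitute their own list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys

from .molprep import MoleculeRecord

logger = logging.getLogger(__name__)

N_FINGERPRINT_BITS = 166


def _num_halogens(mol: Chem.Mol) -> float:
    return float(sum(a.GetAtomicNum() in (9, 17, 35, 53) for a in mol.GetAtoms()))


def _num_aromatic_bonds(mol: Chem.Mol) -> float:
    return float(sum(b.GetIsAromatic() for b in mol.GetBonds()))


def _build_default_registry() -> dict[str, Callable[[Chem.Mol], float]]:
    named = [
        # hydrophobicity, size, polarity
        "MolLogP", "MolMR", "MolWt", "TPSA", "LabuteASA",
        # shape / connectivity
        "BalabanJ", "BertzCT", "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3",
        "Chi0", "Chi1",
        "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n",
        "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
        # counts
        "HeavyAtomCount", "NumHDonors", "NumHAcceptors", "NumRotatableBonds",
        "RingCount", "NumAromaticRings", "NumAliphaticRings",
        "NumSaturatedRings", "NumAromaticHeterocycles",
        "NumAliphaticHeterocycles", "NumHeteroatoms", "NHOHCount", "NOCount",
        "FractionCSP3", "NumValenceElectrons",
    ]
    named += [f"PEOE_VSA{i}" for i in range(1, 15)]
    named += [f"SMR_VSA{i}" for i in range(1, 11)]
    named += ["SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA5", "SlogP_VSA6"]
    registry: dict[str, Callable[[Chem.Mol], float]] = {
        name: getattr(Descriptors, name) for name in named
    }
    registry["NumHalogens"] = _num_halogens
    registry["NumAromaticBonds"] = _num_aromatic_bonds
    return registry


#: Default registry: 68 two-dimensional descriptors.
DEFAULT_REGISTRY = _build_default_registry()

#: Columns that are already on a log scale and must not be re-transformed.
LOG_SCALED_COLUMNS = frozenset({"MolLogP"})


@dataclass
class DescriptorMatrix:
    """Compounds × named real-valued 2D descriptors.

    Rows align with ``ids``, columns with ``names``; all values finite.
    """

    ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError("values shape does not match ids × names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    def subset(self, ids: Sequence[str]) -> "DescriptorMatrix":
        index = {mol_id: i for i, mol_id in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return DescriptorMatrix(list(ids), list(self.names), self.values[rows])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


@dataclass
class FingerprintSet:
    """Compounds × 166-bit structural-key fingerprints.

    ``bits`` is a boolean matrix; ``n_set`` gives the per-molecule popcount
    (the n_A / n_B terms of the Tanimoto coefficient).
    """

    ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.shape[1] != N_FINGERPRINT_BITS:
            raise ValueError(f"fingerprints must be {N_FINGERPRINT_BITS} bits wide")
        if self.bits.shape[0] != len(self.ids):
            raise ValueError("bit matrix rows do not match ids")

    @property
    def n_set(self) -> np.ndarray:
        return self.bits.sum(axis=1)

    def vector(self, mol_id: str) -> np.ndarray:
        return self.bits[self.ids.index(mol_id)]

    def subset(self, ids: Sequence[str]) -> "FingerprintSet":
        index = {mol_id: i for i, mol_id in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return FingerprintSet(list(ids), self.bits[rows])

    def write_tsv(self, path: str | Path) -> None:
        lines = ["id\tfingerprint"]
        for mol_id, row in zip(self.ids, self.bits):
            lines.append(mol_id + "\t" + "".join("1" if b else "0" for b in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FingerprintSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        bits = np.array([[c == "1" for c in s] for s in df["fingerprint"]])
        return cls(list(df["id"]), bits)


def compute_2d_descriptors(
    records: Sequence[MoleculeRecord],
    registry: Optional[Mapping[str, Callable[[Chem.Mol], float]]] = None,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for standardized molecules.

    Fails loudly, naming the molecule and descriptor, on any computation
    error or non-finite result — downstream PCA cannot tolerate silent NaN.
    """
    registry = dict(registry if registry is not None else DEFAULT_REGISTRY)
    names = list(registry)
    values = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        mol = rec.mol()
        for j, name in enumerate(names):
            try:
                v = float(registry[name](mol))
            except Exception as exc:  # pragma: no cover - rdkit raises rarely
                raise RuntimeError(
                    f"descriptor {name!r} failed for molecule {rec.id!r}"
                ) from exc
            if not np.isfinite(v):
                raise RuntimeError(
                    f"descriptor {name!r} is non-finite for molecule {rec.id!r}"
                )
            values[i, j] = v
    return DescriptorMatrix([r.id for r in records], names, values)


def fingerprint_molecule(mol: Chem.Mol) -> np.ndarray:
    """166-bit public MACCS-style key vector for one molecule.

    The toolkit indexes keys 1–166 (bit 0 unused); the returned vector is
    exactly 166 long.  Raises for a molecule with no heavy atoms.
    """
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("cannot fingerprint a molecule with zero heavy atoms")
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(N_FINGERPRINT_BITS, dtype=bool)
    for bit in fp.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = True
    return arr


def compute_fingerprints(records: Sequence[MoleculeRecord]) -> FingerprintSet:
    bits = np.stack([fingerprint_molecule(r.mol()) for r in records]) \
        if records else np.zeros((0, N_FINGERPRINT_BITS), dtype=bool)
    return FingerprintSet([r.id for r in records], bits)


def log_transform(
    matrix: DescriptorMatrix,
    log_scaled: frozenset[str] | set[str] = LOG_SCALED_COLUMNS,
) -> DescriptorMatrix:
    """Log-transform descriptor columns to normalize their distributions.

    Columns flagged as already log-scaled pass through unchanged.  Strictly
    positive columns get a plain natural log; columns containing zeros or
    negatives use the shift rule ``x -> log(x - min(x) + 1)`` so the column
    minimum maps to 0.  Constant columns are transformed like any other but
    trigger a warning, since no monotone transform can normalize them.
    """
    out = matrix.values.copy()
    for j, name in enumerate(matrix.names):
        if name in log_scaled:
            continue
        col = out[:, j]
        if col.size and col.max() == col.min():
            warnings.warn(f"column {name!r} is constant; log cannot normalize it")
        if col.size == 0:
            continue
        m = col.min()
        out[:, j] = np.log(col) if m > 0 else np.log(col - m + 1.0)
    return DescriptorMatrix(list(matrix.ids), list(matrix.names), out)
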