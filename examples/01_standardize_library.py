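"""Curate a small chemical library: salts, ions, duplicates, excluded elements.

Run:  python examples/01_standardize_library.py
"""

from ahrscreen import MoleculeRecord, standardize_library

library = [
    MoleculeRecord(id="71-43-2", smiles="c1ccccc1", name="benzene"),
    MoleculeRecord(id="benzene-dup", smiles="C1=CC=CC=C1", name="benzene again"),
    MoleculeRecord(id="532-32-1", smiles="CCc1ccc(C(=O)[O-])cc1.[Na+]",
                   name="sodium 4-ethylbenzoate"),
    MoleculeRecord(id="78-00-2", smiles="CC[Pb](CC)(CC)CC", name="tetraethyllead"),
    MoleculeRecord(id="75-04-7", smiles="CCN", name="ethylamine"),
    MoleculeRecord(id="broken", smiles="this-is-not-a-structure"),
]

standardized, report = standardize_library(library)

print(f"input records: {report.n_input}")
print(f"kept: {report.n_output}  (excluded elements: {report.n_removed_elements}, "
      f"duplicates: {report.n_removed_duplicates}, parse errors: "
      f"{report.n_removed_parse})")
for mol_id, reason in report.removed_ids:
    print(f"  removed {mol_id}: {reason}")
print("standardized structures:")
for rec in standardized:
    print(f"  {rec.id:14s} {rec.smiles}")

# The sodium counter ion is stripped and the benzoate stays deprotonated; the
# amine is protonated; the duplicate benzene entry and the lead compound are
# removed, and the unparseable record is counted rather than silently lost.
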