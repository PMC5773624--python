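"""Compute 2D descriptors and 166-key fingerprints; compare two known ligands.

Run:  python examples/02_descriptors_and_fingerprints.py
"""

from ahrscreen import MoleculeRecord, compute_2d_descriptors, compute_fingerprints
from ahrscreen.similarity import tanimoto

mols = [
    MoleculeRecord(id="TCDD", smiles="Clc1cc2Oc3cc(Cl)c(Cl)cc3Oc2cc1Cl"),
    MoleculeRecord(id="PCB126", smiles="Clc1ccc(-c2cc(Cl)c(Cl)cc2Cl)cc1Cl"),
    MoleculeRecord(id="nimodipine",
                   smiles="CC(C)OC(=O)C1=C(C)NC(C)=C(C(=O)OCCOC)C1c1cccc([N+](=O)[O-])c1"),
]

matrix = compute_2d_descriptors(mols)
frame = matrix.to_frame()
print(f"descriptor matrix: {frame.shape[0]} compounds x {frame.shape[1]} descriptors")
print(frame[["MolLogP", "NumAromaticRings", "NumHalogens",
             "NumRotatableBonds", "TPSA"]].round(2))

fps = compute_fingerprints(mols)
tc_dioxin_pcb = tanimoto(fps.vector("TCDD"), fps.vector("PCB126"))
tc_dioxin_dhp = tanimoto(fps.vector("TCDD"), fps.vector("nimodipine"))
print(f"\nTanimoto TCDD vs PCB126:     {tc_dioxin_pcb:.2f}")
print(f"Tanimoto TCDD vs nimodipine: {tc_dioxin_dhp:.2f}")

# The two rigid halogenated aromatics share far more structural keys than
# the dioxin shares with the flexible dihydropyridine — exactly the
# typical/atypical split the screening protocol is built around.
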