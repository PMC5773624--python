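"""Hand-written SMILES template sets for the synthetic library generator.

Synthetic stand-ins: short scaffold lists emulating the two chemotypes of
known AhR binders — rigid halogenated-aromatic / fused-polycyclic "typical"
ligands and flexible heteroaromatic "atypical" ligands — plus aliphatic and
small-polar decoy fragments.  Nothing here is fetched from, or claims to
reproduce, any real inventory.
"""

#: Rigid aromatic scaffolds for typical binders; halogens are enumerated on
#: aromatic CH positions at generation time.
TYPICAL_SCAFFOLDS = [
    "c1ccc(-c2ccccc2)cc1",                 # biphenyl (PCB-like)
    "c1ccc2c(c1)Oc1ccccc1O2",              # dibenzo-p-dioxin
    "c1ccc2c(c1)oc1ccccc12",               # dibenzofuran
    "c1ccc2ccccc2c1",                      # naphthalene
    "c1ccc2c(c1)ccc1ccccc12",              # phenanthrene
    "c1cc2ccc3cccc4ccc(c1)c2c34",          # pyrene
    "C1c2ccccc2-c2ccccc21",                # fluorene
    "c1ccc2c(c1)ccc1c2ccc2ccccc21",        # chrysene
    "O=c1cc(-c2ccccc2)oc2ccc3ccccc3c12",   # beta-naphthoflavone core
]

#: Flexible heteroaromatic templates for atypical binders (dihydropyridine,
#: anilide, isoxazole-carboxamide, indole-carbonyl-thiazole, carbazole types).
ATYPICAL_TEMPLATES = [
    "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]",
    "CC(C)C(=O)Nc1ccc([N+](=O)[O-])c(C(F)(F)F)c1",
    "Cc1oncc1C(=O)Nc1ccc(C(F)(F)F)cc1",
    "O=C(c1c[nH]c2ccccc12)c1nccs1",
    "O=Cc1ccc2c(c1)c1ccccc1n2C",
]

#: Terminal groups appended to random alkyl chains when building decoys.
DECOY_GROUPS = [
    "", "O", "N", "OC", "OCC", "C(=O)O", "C(=O)OC", "C(=O)N", "C#N", "S",
    "C(C)O", "OC(C)=O",
]

#: Optional saturated-ring caps for decoys.
DECOY_RINGS = ["", "C1CCCCC1", "C1CCCC1", "C1CCOCC1"]

#: Off-scaffold single-ring aromatic decoy cores: close enough to property
#: space to survive the initial filtration sometimes, but structurally
#: unrelated to the multi-ring reference chemotypes.
DECOY_AROMATIC_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccc(C)cc1", "c1ccc(O)cc1", "c1ccc(OC)cc1",
    "c1ccc(N)cc1", "c1ccc(C(=O)OC)cc1", "c1ccc(CC)cc1", "c1ccc(C(C)C)cc1",
]

#: Substituents sprinkled on aromatic decoy cores.
DECOY_AROMATIC_GROUPS = ["C", "O", "OC", "N", "CC", "C(=O)OC", "Cl", "F"]

#: Decoys carrying elements excluded from the screening domain (exercise the
#: curation filter; all parse and sanitize under RDKit).
EXCLUDED_ELEMENT_DECOYS = [
    "CC[Sn](CC)(CC)CC",
    "CC[Pb](CC)(CC)CC",
    "C[As](C)C",
    "C[Sb](C)C",
    "O=[As](O)(O)c1ccccc1",
    "CCCC[Sn](CCCC)(CCCC)CCCC",
    "C[Sn](C)(C)C",
    "CC(=O)O[Pb]OC(C)=O",
    "O=[As](O)(O)C",
    "C[As](C)(C)=O",
]
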