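# Methods

`ahrscreen` implements a consensus virtual-screening protocol for
prioritizing potential aryl hydrocarbon receptor (AhR) ligands in large
chemical inventories. The protocol combines two ligand-based enrichments
and one structure-based enrichment, preceded by a chemical-space filtration
and followed by majority voting. This note records the model, its
parameters and the design decisions that were genuinely open.

## The screening model

**Reference sets.** Known AhR binders are defined by competitive-binding
potency (lowest reported IC50/Ki/Kd) at or below 10 µM, boundary inclusive.
When a compound has several assay values the minimum (most potent) is used;
compounds without potency data are excluded from the reference set rather
than guessed. Binders come in two chemotypes: *typical* ligands (small,
rigid, halogenated aromatics and fused polycyclics — dioxins, PCBs, PAHs)
and *atypical* ligands (flexible heteroaromatics with additional functional
groups — dihydropyridines, anilides, carbazoles).

**Curation.** Structures are standardized before any computation: the
largest carbon-containing fragment is kept (counter ions stripped; ties by
heavy-atom count, then canonical-SMILES order), carboxylic/sulfonic/
phosphonic acids are deprotonated, aliphatic amines/amidines/guanidines are
protonated, and duplicates are collapsed on the canonical SMILES of the
standardized structure with stereochemistry retained. Compounds containing
Al, As, Ba, Bi, Cd, Co, Cr, Mn, Ni, Pb, Sb, Sn, Sr, Ti or Zr — elements
without reliable descriptor/force-field parameterization — are removed
whole, judged on the structure as supplied (a compound delivered as an
excluded-element salt is removed, not rescued by salt stripping). The
"strong acid/base" policy is operationalized as a fixed transformation
list; the functional groups covered are a package choice, since only the
policy, not the group list, is part of the protocol definition.

**Descriptors and fingerprints.** Every compound is characterized by 68
two-dimensional descriptors covering hydrophobicity (Crippen logP),
polarity (PEOE_VSA partial-charge surface-area bins), size, flexibility,
aromaticity and shape (Balaban J, Kier kappa shape indices, connectivity
chis), plus the public 166-key MACCS-style structural fingerprint. The
registry is an explicit name → function mapping and is fully replaceable;
the default reproduces every descriptor family the protocol names and pads
with standard 2D descriptors to 68 columns. Key-definition dialects of the
166 structural keys differ slightly between toolkits; Tanimoto values
computed here carry a documented ±0.02 tolerance against values printed by
other software. Three-dimensional descriptors (principal moments of
inertia, maximal interatomic distance, quantum-chemical orbital energies)
are deliberately out of scope: the screening branch operates on 2D
descriptors only.

**PCA chemical space and applicability domain.** Screening PCAs are fitted
on unit-variance-scaled descriptors via SVD of the centered/scaled matrix.
Eigenvalues are score variances with the n−1 convention, so on
unit-variance data they sum to the number of descriptors; a component is
*significant* when its eigenvalue is ≥ 2 (at least one component is always
retained). Applicability-domain (AD) membership of a compound requires both

- Hotelling's T² = Σₐ tₐ²/λₐ over the significant components at or below
  the 95% limit A(n−1)/(n−A)·F₀.₉₅(A, n−A), and
- DModX — the residual SD of the descriptor reconstruction, normalized by
  the training pooled residual SD s₀ with (n−A−1)(p−A) degrees of freedom —
  at or below √F₀.₉₅(p−A, (n−A−1)(p−A)).

The F-ratio form of the DModX limit is the conventional one; the exact
correction used by commercial PCA software is unpublished, so the formula
above is the package's documented choice and is tested against its own
first-principles recomputation. Constant descriptor columns are dropped
with a warning before fitting (detected with a relative tolerance so
round-off does not masquerade as variance). If a model fits the training
data exactly (zero residual variance), DModX is defined as 0 and the DModX
limit is skipped with a warning; membership then rests on T² alone.

**Initial filtration.** Two branches run in parallel and their union feeds
the screening methods. The *typical* branch fits a PCA on the binder
reference set alone and keeps candidates inside that model's 95% AD — the
domain is defined relative to the binders, so the model is fitted on them
only (the protocol text does not state the fitting set; this is the
package's documented reading). The *atypical* branch log-transforms the
descriptors (natural log for strictly positive columns; x → log(x − min + 1)
for columns containing zeros or negatives; columns already on a log scale,
e.g. logP, pass through), fits a PCA on the atypical references together
with the candidates, and keeps candidates within Euclidean distance 1.5
(inclusive) of any atypical reference in the significant-component score
space. The much tighter distance cutoff in this branch reflects the
compressed, log-transformed scale.

**Parallel enrichments.** On the filtration survivors:

1. *Structural fingerprints* — a candidate is a hit when its best Tanimoto
   coefficient TC = n_same/(n_A + n_B − n_same) over the reference binders
   is ≥ 0.60 (inclusive). The maximizing reference is recorded.
2. *Nearest neighbors* — in the significant-component score space of a PCA
   fitted on references ∪ survivors (raw, unit-variance-scaled
   descriptors), each reference keeps its candidates within ED ≤ 5.0,
   nearest first, truncated at 10 neighbors. Distance ties at the capacity
   boundary resolve by candidate-id lexicographic order, making the result
   order-independent. The hit set is the union over references.
3. *Docking-score gate* — binding free energies (ΔG_bind, kcal/mol) arrive
   as an external table (the docking engine itself is behind a file
   contract; commercial docking and rescoring are not reimplemented). Per
   compound the minimum ΔG_bind over all stereoisomers and poses is kept,
   ties resolving to the lexicographically smallest stereoisomer and pose.
   The gate passes candidates at or below mean + 1 SD of the reference
   binders' best-pose scores. The SD is the sample SD (n−1); with 65
   references the difference from the population SD is negligible, but the
   choice is fixed and documented. Compounds with no score records are
   reported as failed in docking and excluded, never silently passed.

**Consensus and evaluation.** A compound is a consensus hit with ≥ 2 of 3
method votes. Predictions are evaluated on an explicit universe — labeled
compounds that survived filtration — with accuracy, sensitivity and
specificity; a zero denominator yields "undefined", never 0, and summary
rounding is half-up to two decimals. Ambiguous activity labels are
excluded before evaluation.

**Clustering.** Docking-gate hits are grouped with the known binders by
agglomerative clustering on Tanimoto distances (1 − TC) using the
Lance–Williams flexible-beta update with β = 0.25, α = (1−β)/2 = 0.375,
γ = 0. Because 2α + β = 1 the linkage is monotone; non-decreasing merge
heights are asserted on every run. Merge order is by minimum current
distance with ties broken on the smallest cluster-index pair, and flat
cuts label each cluster by its lexicographically smallest member, so
results are independent of input order. scipy's linkage implementations do
not expose the flexible-beta update, hence the in-package implementation;
it is verified against a naive rebuild-the-matrix oracle.

## The synthetic-data generator

Real screening inventories and binder panels are not redistributable, so
the generator builds, from one seed, libraries with the statistical and
structural properties the protocol assumes:

- *references*: 61 typical binders (halogen-enumerated biphenyl, dioxin,
  dibenzofuran, PAH and naphthoflavone scaffolds) and 5 atypical binders
  (dihydropyridine, anilide, isoxazole-carboxamide, indole-carbonyl-
  thiazole, carbazole templates), 66 in total, all with potency ≤ 10 µM;
- *candidates* (default 1000): 60 planted single-substituent analogs of the
  references (ground-truth "should-hit"), a 10-compound quota of
  excluded-element decoys exercising curation, and aliphatic/small-polar/
  single-ring-aromatic decoys ("should-miss");
- *docking scores*: per compound a base draw from Normal(−112.5, 13.2)
  kcal/mol for binder-like compounds or Normal(−70, 15) for decoys — the
  decoy anchor is an artifact choice giving clear but overlapping
  separation — with 10 poses per stereoisomer offset by non-negative
  jitter whose minimum is zero, so the best pose reproduces the base draw;
- *labels*: planted compounds active with probability 0.8, decoys 0.1,
  making the label-based metrics deliberately noisy.

What the generator does **not** emulate: the composition of any real
industrial inventory, real binder identities, tautomerism, activity
cliffs, or correlated assay noise. Passing the end-to-end recovery test
therefore demonstrates internal consistency of the pipeline under its own
assumptions, not prospective performance on real inventories.

## Calibration and problem sizes

On the default 1000-compound campaign (benchmark seed 1) the ≥2-of-3
consensus recovers planted analogs with precision ≈ 0.92 and recall ≈ 0.75;
the asserted bounds are precision ≥ 0.7 and recall ≥ 0.6 at that documented
seed. Recall is limited almost entirely by the 95% AD filtration — a
single-edit analog of a reference occasionally falls outside the binders'
own 95% domain, exactly as a 95% envelope should behave — and across other
seeds recall fluctuates around 0.6–0.77. Unit and property tests use
reduced campaigns (120–300 candidates, 25–35 references) and small random
instances (PCA oracle at n = 50, p = 10; clustering oracle at n ≤ 8);
these sizes make every oracle comparison exact and keep the whole suite in
seconds.

## Numerical choices and degenerate inputs

- Cutoff boundaries (TC 0.60, ED 1.5/5.0, ΔG gate) are all inclusive,
  consistent with the "at or below" convention of the potency rule.
- PCA rank is truncated at singular values below 1e-10 of the largest;
  loadings orthonormality and eigenvalue ordering are validated at 1e-8.
- Tanimoto is undefined (raises) for two all-zero fingerprints; a zero
  heavy-atom molecule cannot be fingerprinted.
- Reference cutoff requires n ≥ 2 scores; with SD 0 the gate passes exact
  matches only.
- Descriptor computation fails loudly, naming molecule and descriptor, on
  any error or non-finite value; there is no silent NaN path.

## Known limitations

- The 68-descriptor registry reproduces the named descriptor families with
  open-toolkit implementations; bin boundaries of surface-area descriptors
  and key definitions of the 166 structural keys differ slightly from
  commercial toolkits (the ±0.02 TC tolerance above).
- Docking and rescoring are consumed, not computed; the gate is only as
  good as the supplied ΔG_bind table.
- The protocol ranks candidates by similarity to known binders and
  predicted binding; it cannot distinguish agonists from antagonists, and
  actives that work without receptor binding are invisible to it.
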