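"""Fit a PCA chemical-space model and test applicability-domain membership.

Run:  python examples/03_chemical_space_and_ad.py
"""

from ahrscreen import (
    GeneratorConfig,
    applicability_domain,
    compute_2d_descriptors,
    fit_pca,
    make_candidate_library,
    make_reference_binders,
)

config = GeneratorConfig(seed=4, n_candidates=100, n_typical_refs=30,
                         n_atypical_refs=5, n_planted_analogs=15,
                         n_excluded_decoys=0)
typical, atypical = make_reference_binders(config)
library = make_candidate_library(config, typical + atypical)

binder_space = compute_2d_descriptors(typical + atypical)
model = fit_pca(binder_space)
print(f"binder model: {model.n_significant} significant PCs "
      f"(eigenvalue >= 2 rule), R2X cumulative "
      f"{model.r2x[: model.n_significant].sum():.2f}")
print(f"95% limits: T2 <= {model.t2_limit_95:.2f}, DModX <= "
      f"{model.dmodx_crit_95:.2f}")

candidates = compute_2d_descriptors(library.records)
ad = applicability_domain(model, candidates)
inside = ad.inside_ids()
planted_in = sum(1 for i in library.should_hit_ids if i in inside)
decoys_in = len(inside) - planted_in
print(f"\ncandidates inside the binder applicability domain: {len(inside)}/100")
print(f"  planted binder analogs inside: {planted_in}/{len(library.should_hit_ids)}")
print(f"  decoys inside:                 {decoys_in}")

# Structural analogs of the binders fall inside the binders' own 95% domain;
# aliphatic decoys land far outside the model plane (high DModX) or far from
# the model center (high T2) and are filtered out before any screening step.
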