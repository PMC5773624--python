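"""The two ligand-based enrichments: fingerprint TC and PC-space neighbors.

Run:  python examples/04_ligand_based_screens.py
"""

import numpy as np

from ahrscreen import (
    GeneratorConfig,
    ScoreMatrix,
    compute_2d_descriptors,
    compute_fingerprints,
    fingerprint_screen,
    fit_pca,
    make_candidate_library,
    make_reference_binders,
    nearest_neighbor_screen,
    project,
)
from ahrscreen.descriptors import DescriptorMatrix

config = GeneratorConfig(seed=5, n_candidates=150, n_typical_refs=25,
                         n_atypical_refs=5, n_planted_analogs=20,
                         n_excluded_decoys=0)
typical, atypical = make_reference_binders(config)
refs = typical + atypical
library = make_candidate_library(config, refs)

# fingerprint screen at the TC >= 0.60 cutoff
ref_fps = compute_fingerprints(refs)
cand_fps = compute_fingerprints(library.records)
fp_hits, table = fingerprint_screen(ref_fps, cand_fps, tc_cutoff=0.60)
best = max(table, key=lambda h: h.value)
print(f"fingerprint hits (TC >= 0.60): {len(fp_hits)}")
print(f"  best pair: {best.candidate_id} vs {best.reference_id} "
      f"(TC = {best.value:.2f})")

# nearest neighbors at ED <= 5.0, max 10 per reference, in a joint PC space
ref_desc = compute_2d_descriptors(refs)
cand_desc = compute_2d_descriptors(library.records)
joint = DescriptorMatrix(ref_desc.ids + cand_desc.ids, ref_desc.names,
                         np.vstack([ref_desc.values, cand_desc.values]))
model = fit_pca(joint)
scores = project(model, joint)
n_ref = len(refs)
nn_hits, lists = nearest_neighbor_screen(
    ScoreMatrix(scores.ids[:n_ref], scores.scores[:n_ref], scores.model_tag),
    ScoreMatrix(scores.ids[n_ref:], scores.scores[n_ref:], scores.model_tag),
    ed_cutoff=5.0, max_neighbors=10)
print(f"\nnearest-neighbor hits (ED <= 5.0 in {model.n_significant}-PC space): "
      f"{len(nn_hits)}")
busiest = max(lists, key=lambda nl: len(nl.neighbors))
print(f"  busiest reference {busiest.reference_id}: "
      f"{len(busiest.neighbors)} neighbors (capacity 10)")

planted = library.should_hit_ids
print(f"\nplanted analogs recovered by either screen: "
      f"{len((fp_hits | nn_hits) & planted)}/{len(planted)}")

# The two screens see different things: TC finds shared substructure keys,
# the PC-space distance finds matching global property profiles; their union
# recovers more planted analogs than either alone.
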