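"""Adjusted cosine similarity on binary gene/pathway profiles.

Builds three tiny disease profiles, computes gene- and pathway-level ACS
and the combined two-level similarity, and shows the degenerate-vector
fallback in action.
"""

import numpy as np

from ddcm import EntityKind, EntityProfile, FeatureSpace, Level, acs
from ddcm.similarity import combined_similarity, level_similarity

space = FeatureSpace(
    gene_ids=("G1", "G2", "G3", "G4", "G5"),
    pathway_ids=("P1", "P2", "P3"),
)
profiles = [
    EntityProfile("lung_ca", EntityKind.DISEASE, frozenset({"G1", "G2"}), frozenset({"P1"})),
    EntityProfile("cns_ca", EntityKind.DISEASE, frozenset({"G1", "G3"}), frozenset({"P1", "P2"})),
    # all five genes -> constant gene vector, similarity must fall back to pathways
    EntityProfile("pan_ca", EntityKind.DISEASE,
                  frozenset({"G1", "G2", "G3", "G4", "G5"}), frozenset({"P2"})),
]

print("ACS of two raw vectors (phi of their 2x2 table):")
print("  acs([1,1,0,0,0], [1,0,1,0,0]) =", round(acs([1, 1, 0, 0, 0], [1, 0, 1, 0, 0]), 5))

gene = level_similarity(profiles, space, Level.GENE)
pathway = level_similarity(profiles, space, Level.PATHWAY)
combined = combined_similarity(gene, pathway)

names = [p.entity_id for p in profiles]
for tag, sim in (("gene", gene), ("pathway", pathway), ("combined", combined)):
    print(f"\n{tag}-level similarity ({', '.join(names)}):")
    print(np.round(sim.values, 3))

print(
    "\nlung_ca/cns_ca share one of three distinct genes -> modest positive "
    "gene ACS; pan_ca's gene vector is constant (all ones), so its combined "
    "similarities use the pathway level alone."
)
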