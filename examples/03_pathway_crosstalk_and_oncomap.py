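"""Pathway redundancy collapse, crosstalk network and canonical mapping.

Starting from a hand-written enrichment result, this script collapses
near-duplicate terms (enriched-gene Jaccard > 0.60), links crosstalking
representatives (Jaccard >= 0.25), clusters the network by greedy
modularity, and projects each representative onto the canonical
oncogenic signalling pathways and carcinogenesis process categories.
"""

import pandas as pd

from moanet.oncomap import map_pathways
from moanet.pathway_network import (build_crosstalk_network, cluster_pathways,
                                    collapse_redundant, jaccard)

rows = pd.DataFrame([
    # two database variants of the same NRF2 response: J = 5/6 > 0.60
    {"term": "wikipathways::NRF2 pathway", "fdr": 0.001, "k": 6,
     "overlap_genes": frozenset({"NFE2L2", "KEAP1", "GCLC", "GCLM", "NQO1",
                                 "TXNRD1"})},
    {"term": "reactome::Nuclear receptor meta-pathway", "fdr": 0.004, "k": 5,
     "overlap_genes": frozenset({"NFE2L2", "KEAP1", "GCLC", "GCLM", "NQO1"})},
    # shares 3 of 9 genes with the NRF2 overlap: crosstalk band
    {"term": "kegg::Apoptosis", "fdr": 0.010, "k": 6,
     "overlap_genes": frozenset({"NQO1", "TXNRD1", "GCLC", "CASP3", "CASP9",
                                 "BAX"})},
    # disjoint from both: isolated node in the crosstalk network
    {"term": "wikipathways::VEGFA-VEGFR2 Signaling Pathway", "fdr": 0.02,
     "k": 3, "overlap_genes": frozenset({"VEGFA", "KDR", "NRP1"})},
])

reps, redundancy_map = collapse_redundant(rows)
print("representatives after redundancy collapse:")
for member, rep in sorted(redundancy_map.items()):
    marker = "=" if member == rep else "->"
    print(f"  {member} {marker} {rep}")

pg = build_crosstalk_network(reps)
cluster_pathways(pg)
print("\ncrosstalk edges (Jaccard of enriched gene sets):")
print(pg.edge_table().to_string(index=False))
print("\nclusters:")
print(pg.cluster_table().to_string(index=False))

nrf2 = rows.iloc[0]["overlap_genes"]
apop = rows.iloc[2]["overlap_genes"]
print(f"\nNRF2 vs Apoptosis Jaccard = {jaccard(nrf2, apop):.3f} "
      "(>= 0.25, hence the edge above)")

# direction comes from which directional subnetwork enriched each term
up = pd.DataFrame({"term": ["wikipathways::NRF2 pathway"], "fdr": [0.002]})
down = pd.DataFrame({"term": ["kegg::Apoptosis"], "fdr": [0.01]})
table = map_pathways(reps, up, down)
print("\ncanonical oncogenic pathway / process mapping:")
print(table[["term", "canonical", "category", "direction"]]
      .to_string(index=False))
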