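"""Jaccard pathway-pathway networks: redundancy collapse, crosstalk, clustering.

Pathway similarity is the Jaccard index of the *enriched* gene sets
(the subnetwork-pathway overlaps), J = |Gi ∩ Gj| / |Gi ∪ Gj|. Pairs with
J > 0.60 are treated as redundant (one family representative is kept);
pairs of representatives with J >= 0.25 are linked as crosstalk edges.
Clusters come from greedy (Clauset-Newman-Moore) modularity maximization
on the unweighted crosstalk graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard",
    "collapse_redundant",
    "build_crosstalk_network",
    "cluster_pathways",
    "PathwayGraph",
]

REDUNDANCY_CUTOFF = 0.60
CROSSTALK_CUTOFF = 0.25


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two gene sets."""
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    union = len(set(a) | set(b))
    return len(set(a) & set(b)) / union


def collapse_redundant(rows: pd.DataFrame,
                       redundancy_cutoff: float = REDUNDANCY_CUTOFF,
                       ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Collapse redundant pathway terms (J strictly above the cutoff).

    An auxiliary graph links terms whose enriched-gene-set Jaccard
    exceeds ``redundancy_cutoff``; within each connected component the
    representative is the term with the smallest fdr, then the largest
    overlap k, then the lexicographically smallest name. Returns the
    representative rows and a member->representative map.
    """
    if rows.empty:
        return rows, {}
    terms = list(rows["term"])
    sets = dict(zip(rows["term"], rows["overlap_genes"]))
    aux = nx.Graph()
    aux.add_nodes_from(terms)
    for i, ti in enumerate(terms):
        for tj in terms[i + 1:]:
            if jaccard(sets[ti], sets[tj]) > redundancy_cutoff:
                aux.add_edge(ti, tj)
    meta = rows.set_index("term")
    redundancy_map: dict[str, str] = {}
    reps: list[str] = []
    for comp in nx.connected_components(aux):
        rep = min(comp, key=lambda t: (meta.at[t, "fdr"], -meta.at[t, "k"], t))
        reps.append(rep)
        for member in comp:
            redundancy_map[member] = rep
    keep = rows["term"].isin(reps)
    logger.info("redundancy collapse: %d terms -> %d representatives",
                len(terms), int(keep.sum()))
    return rows.loc[keep].reset_index(drop=True), redundancy_map


@dataclass
class PathwayGraph:
    """Crosstalk network over representative pathway terms."""

    graph: nx.Graph
    redundancy_cutoff: float = REDUNDANCY_CUTOFF
    crosstalk_cutoff: float = CROSSTALK_CUTOFF
    clusters: dict[str, int] = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"term_i": a, "term_j": b, "jaccard": d["weight"]}
                for a, b, d in sorted(self.graph.edges(data=True))]
        return pd.DataFrame(rows, columns=["term_i", "term_j", "jaccard"])

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": t, "cluster": c} for t, c in sorted(self.clusters.items())],
            columns=["term", "cluster"])


def build_crosstalk_network(representatives: pd.DataFrame,
                            crosstalk_cutoff: float = CROSSTALK_CUTOFF,
                            redundancy_cutoff: float = REDUNDANCY_CUTOFF,
                            ) -> PathwayGraph:
    """Link representative terms sharing at least ``crosstalk_cutoff`` Jaccard.

    The cutoff is inclusive (J exactly at the threshold gets an edge);
    isolated terms are kept as singleton nodes.
    """
    g = nx.Graph()
    terms = list(representatives["term"])
    sets = dict(zip(representatives["term"], representatives["overlap_genes"]))
    for term in terms:
        row = representatives.loc[representatives["term"] == term].iloc[0]
        g.add_node(term, fdr=float(row["fdr"]), k=int(row["k"]))
    for i, ti in enumerate(terms):
        for tj in terms[i + 1:]:
            j = jaccard(sets[ti], sets[tj])
            if j >= crosstalk_cutoff:
                g.add_edge(ti, tj, weight=j)
    return PathwayGraph(graph=g, redundancy_cutoff=redundancy_cutoff,
                        crosstalk_cutoff=crosstalk_cutoff)


def cluster_pathways(pg: PathwayGraph, weighted: bool = False) -> dict[str, int]:
    """Greedy modularity clustering of the crosstalk graph.

    Runs Clauset-Newman-Moore agglomeration on the unweighted graph by
    default (``weighted=True`` uses the Jaccard weights). Isolated nodes
    become singleton clusters. Cluster ids are assigned deterministically
    in order of each cluster's lexicographically smallest member.
    """
    g = pg.graph
    if g.number_of_nodes() == 0:
        pg.clusters = {}
        return pg.clusters
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
    else:
        weight = "weight" if weighted else None
        communities = [set(c) for c in greedy_modularity_communities(g, weight=weight)]
    communities.sort(key=lambda c: min(c))
    clusters = {term: idx for idx, comm in enumerate(communities) for term in comm}
    pg.clusters = clusters
    return clusters
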