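"""Hub-gene ranking by degree and betweenness centrality.

Betweenness is computed on the subnetwork itself (not the whole
interactome), unnormalized, over unordered source-target pairs with
endpoints excluded and fractional credit across equal-length shortest
paths — the raw-score convention of CytoNCA-style network analysis.
Genes are ranked by the mean of their degree rank and betweenness rank.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd
from scipy.stats import rankdata

from .subnetwork import SubnetworkSolution

__all__ = ["compute_centrality", "top_genes"]


def _as_graph(s: SubnetworkSolution | nx.Graph) -> nx.Graph:
    if isinstance(s, nx.Graph):
        return s
    g = nx.Graph()
    g.add_nodes_from(s.nodes)
    g.add_edges_from(s.edges)
    return g


def compute_centrality(s: SubnetworkSolution | nx.Graph,
                       normalized: bool = False) -> pd.DataFrame:
    """Degree and betweenness table for a subnetwork.

    Returns a DataFrame indexed by gene with columns degree, betweenness,
    rank_degree, rank_betweenness (descending ranks, ties share the mean
    rank) and composite_rank (1..n ordering by mean-of-ranks, final ties
    lexicographic).
    """
    g = _as_graph(s)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centrality of an empty subnetwork")
    genes = sorted(g.nodes)
    degree = [g.degree(n) for n in genes]
    bc = nx.betweenness_centrality(g, normalized=normalized)
    betweenness = [bc[n] for n in genes]
    # descending ranks: largest value gets rank 1; ties share the mean rank
    rank_deg = rankdata([-d for d in degree], method="average")
    rank_bet = rankdata([-b for b in betweenness], method="average")
    composite = (rank_deg + rank_bet) / 2.0
    table = pd.DataFrame({
        "degree": degree,
        "betweenness": betweenness,
        "rank_degree": rank_deg,
        "rank_betweenness": rank_bet,
        "composite_score": composite,
    }, index=pd.Index(genes, name="gene"))
    order = table.sort_values("composite_score", kind="stable").index  # lex ties: index pre-sorted
    table["composite_rank"] = pd.Series(range(1, len(order) + 1), index=order)
    return table


def top_genes(table: pd.DataFrame, n: int = 5) -> list[str]:
    """The top-n hub genes by composite rank (mean of degree and betweenness ranks)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > len(table):
        warnings.warn(f"requested top {n} of {len(table)} genes; returning all")
        n = len(table)
    ordered = table.sort_values("composite_rank").index
    return [str(g) for g in ordered[:n]]
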