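"""Protein-protein interaction network input and indicator attachment.

The prior network is an undirected simple graph over uppercased official
gene symbols. Supported inputs: a 2-column tab/space edge list, SIF, and
BioGRID TAB3 (restricted to the two official-symbol columns, optionally
keeping physical interactions only).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .expression import IndicatorVector

logger = logging.getLogger(__name__)

__all__ = ["NetworkError", "read_network", "write_edge_list", "attach_indicator"]


class NetworkError(ValueError):
    """Raised on malformed or empty network inputs."""


def _add_edge(g: nx.Graph, a: str, b: str) -> None:
    a, b = a.strip().upper(), b.strip().upper()
    if not a or not b or a == b:
        return
    g.add_edge(a, b)


def _read_edge_tsv(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise NetworkError(f"{path}:{lineno}: expected two columns")
            _add_edge(g, parts[0], parts[1])
    return g


def _read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:  # isolated node, legal SIF
                g.add_node(parts[0].strip().upper())
            elif len(parts) == 2:
                raise NetworkError(f"{path}:{lineno}: SIF line has a relation "
                                   "but no target node")
            else:
                for target in parts[2:]:
                    _add_edge(g, parts[0], target)
    return g


def _read_biogrid_tab3(path, physical_only: bool = True) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().lstrip("#"): c for c in df.columns}
    a_col = cols.get("official symbol interactor a")
    b_col = cols.get("official symbol interactor b")
    if a_col is None or b_col is None:
        raise NetworkError(f"{path}: official-symbol columns not found")
    type_col = cols.get("experimental system type")
    if physical_only and type_col is not None:
        df = df[df[type_col].str.lower() == "physical"]
    g = nx.Graph()
    for a, b in zip(df[a_col], df[b_col]):
        if isinstance(a, str) and isinstance(b, str):
            _add_edge(g, a, b)
    return g


def read_network(path, format: str = "edge_tsv", physical_only: bool = True) -> nx.Graph:
    """Read and sanitize an interactome.

    Symbols are uppercased and whitespace-stripped; self-loops and
    duplicate edges are removed. An interactome empty after sanitization
    is an error. The whole network is kept — the subnetwork search copes
    with disconnected graphs naturally.
    """
    readers = {
        "edge_tsv": _read_edge_tsv,
        "sif": _read_sif,
        "biogrid_tab3": lambda p: _read_biogrid_tab3(p, physical_only=physical_only),
    }
    if format not in readers:
        raise NetworkError(f"unknown network format {format!r}")
    g = readers[format](path)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise NetworkError(f"{path}: network empty after sanitization")
    logger.info("read interactome: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a deterministic 2-column TSV edge list (sorted endpoints/lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def attach_indicator(g: nx.Graph, ind: IndicatorVector) -> tuple[dict[str, int], int]:
    """Project an indicator vector onto the interactome nodes.

    Genes absent from the indicator default to 0 (unmeasured genes are
    treated as not differentially expressed). Matching is case-insensitive
    via uppercasing. Returns the node->{0,1} map and the count of
    indicator-1 nodes present in the graph.
    """
    upper = {str(k).upper(): v for k, v in ind.values.items()}
    mapped = {node: int(upper.get(node, 0)) for node in g.nodes}
    count = sum(mapped.values())
    if count == 0:
        logger.warning("no indicator-1 genes map onto the interactome; "
                       "the subnetwork stage will be empty")
    return mapped, count
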