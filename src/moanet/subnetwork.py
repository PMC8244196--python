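"""K-exception active-subnetwork extraction.

The optimization problem: given an interactome and binary node
indicators (1 = differentially expressed), find a connected induced
subgraph maximizing the number of indicator-1 nodes while containing at
most K indicator-0 "exception" nodes. This is the INES-style connected
subnetwork formulation. Two solvers are provided: a deterministic greedy
(used by the pipeline) and an exact enumerator over exception subsets
(used as an oracle on small graphs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .expression import IndicatorVector, binarize
from .interactome import attach_indicator

logger = logging.getLogger(__name__)

__all__ = [
    "SubnetworkSolution",
    "greedy_max_subnetwork",
    "exact_max_subnetwork",
    "extract_all_variants",
]


@dataclass(frozen=True)
class SubnetworkSolution:
    """A connected subnetwork with at most K exception (indicator-0) nodes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    exceptions: tuple[str, ...]
    variant: str = "all"

    @property
    def de_count(self) -> int:
        return len(self.nodes) - len(self.exceptions)

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def node_table(self, ind: dict[str, int] | None = None) -> pd.DataFrame:
        exc = set(self.exceptions)
        return pd.DataFrame({
            "gene": list(self.nodes),
            "indicator": [0 if n in exc else 1 for n in self.nodes]
            if ind is None else [ind.get(n, 0) for n in self.nodes],
            "is_exception": [n in exc for n in self.nodes],
        })


def _make_solution(g: nx.Graph, nodes: set[str], ind: dict[str, int],
                   variant: str) -> SubnetworkSolution:
    ordered = tuple(sorted(nodes))
    sub = g.subgraph(nodes)
    edges = tuple(sorted(tuple(sorted(e)) for e in sub.edges()))
    exceptions = tuple(sorted(n for n in nodes if ind.get(n, 0) == 0))
    return SubnetworkSolution(nodes=ordered, edges=edges,
                              exceptions=exceptions, variant=variant)


def _validate(sol: SubnetworkSolution, g: nx.Graph, k: int) -> SubnetworkSolution:
    if sol.is_empty:
        return sol
    sub = g.subgraph(sol.nodes)
    assert nx.is_connected(sub), "solution must induce a connected subgraph"
    assert len(sol.exceptions) <= k, "exception budget exceeded"
    return sol


def _reachable_gain(g: nx.Graph, candidate: set[str], via: str,
                    positives: set[str]) -> int:
    """Indicator-1 nodes newly reachable through `via` along indicator-1-only paths."""
    allowed = (positives - candidate) | {via}
    seen = {via}
    stack = [via]
    gain = 0
    while stack:
        u = stack.pop()
        for w in g.neighbors(u):
            if w in allowed and w not in seen:
                seen.add(w)
                if w in positives:
                    gain += 1
                stack.append(w)
    return gain


def _grow_from_seed(g: nx.Graph, ind: dict[str, int], k: int, seed: str,
                    positives: set[str]) -> tuple[set[str], set[str]]:
    nodes = {seed}
    exceptions: set[str] = set()
    while True:
        frontier = {w for u in nodes for w in g.neighbors(u)} - nodes
        pos_frontier = sorted(w for w in frontier if ind[w] == 1)
        if pos_frontier:
            nodes.update(pos_frontier)
            continue
        if len(exceptions) >= k:
            break
        best, best_gain = None, 0
        for w in sorted(w for w in frontier if ind[w] == 0):
            gain = _reachable_gain(g, nodes, w, positives)
            if gain > best_gain:  # ties keep the lexicographically first
                best, best_gain = w, gain
        if best is None:
            break
        nodes.add(best)
        exceptions.add(best)
    return nodes, exceptions


def _solution_key(nodes: set[str], exceptions: set[str]) -> tuple:
    return (-(len(nodes) - len(exceptions)), len(exceptions), tuple(sorted(nodes)))


def greedy_max_subnetwork(g: nx.Graph, ind: dict[str, int], k: int = 5,
                          variant: str = "all") -> SubnetworkSolution:
    """Deterministic greedy K-exception subnetwork search.

    One candidate is grown from every indicator-1 node (in lexicographic
    order). Growth absorbs every adjacent indicator-1 node; when none
    remains, and exception budget is left, it admits the indicator-0
    neighbor that unlocks the most indicator-1 nodes along
    indicator-1-only paths (ties lexicographic; a neighbor unlocking no
    new indicator-1 node is never admitted). The best candidate wins by
    (de_count desc, fewer exceptions, lexicographically smallest node
    list). The result is locally maximal: no indicator-1 node adjacent to
    it remains unadded.
    """
    if k < 0:
        raise ValueError("K must be non-negative")
    positives = {n for n in g.nodes if ind.get(n, 0) == 1}
    if not positives:
        logger.warning("no indicator-1 nodes in graph; returning empty solution")
        return SubnetworkSolution(nodes=(), edges=(), exceptions=(), variant=variant)
    best: tuple | None = None
    best_nodes: set[str] = set()
    for seed in sorted(positives):
        nodes, exc = _grow_from_seed(g, ind, k, seed, positives)
        key = _solution_key(nodes, exc)
        if best is None or key < best:
            best, best_nodes = key, nodes
    sol = _make_solution(g, best_nodes, ind, variant)
    return _validate(sol, g, k)


def exact_max_subnetwork(g: nx.Graph, ind: dict[str, int], k: int = 5,
                         variant: str = "all",
                         max_nodes: int = 20) -> SubnetworkSolution:
    """Provably optimal K-exception subnetwork on small graphs.

    Every optimal solution is a connected component of the subgraph
    induced by the indicator-1 nodes plus some exception set E (|E| <= K),
    so enumerating exception subsets and their components suffices.
    Guarded to graphs of at most ``max_nodes`` nodes.
    """
    if g.number_of_nodes() > max_nodes:
        raise ValueError(f"exact solver limited to {max_nodes} nodes, "
                         f"got {g.number_of_nodes()}")
    positives = {n for n in g.nodes if ind.get(n, 0) == 1}
    if not positives:
        logger.warning("no indicator-1 nodes in graph; returning empty solution")
        return SubnetworkSolution(nodes=(), edges=(), exceptions=(), variant=variant)
    zeros = sorted(n for n in g.nodes if ind.get(n, 0) == 0)
    best: tuple | None = None
    best_nodes: set[str] = set()
    for size in range(min(k, len(zeros)) + 1):
        for exc_set in combinations(zeros, size):
            sub = g.subgraph(positives | set(exc_set))
            for comp in nx.connected_components(sub):
                comp_exc = comp - positives
                if not comp & positives:
                    continue
                key = _solution_key(comp, comp_exc)
                if best is None or key < best:
                    best, best_nodes = key, set(comp)
    sol = _make_solution(g, best_nodes, ind, variant)
    return _validate(sol, g, k)


@dataclass
class VariantSolutions:
    """Subnetwork solutions for the all/up/down indicator variants."""

    solutions: dict[str, SubnetworkSolution] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for variant in ("all", "up", "down"):
            sol = self.solutions[variant]
            rows.append({"variant": variant, "genes": len(sol.nodes),
                         "interactions": len(sol.edges),
                         "de_count": sol.de_count,
                         "exceptions": len(sol.exceptions)})
        return pd.DataFrame(rows)


def extract_all_variants(g: nx.Graph, de: pd.DataFrame, fc_cutoff: float = 2.0,
                         fdr_cutoff: float = 5e-3, k: int = 5) -> VariantSolutions:
    """Run the greedy solver once per indicator variant (all, up, down)."""
    indicators = binarize(de, fc_cutoff=fc_cutoff, fdr_cutoff=fdr_cutoff)
    out = VariantSolutions()
    for variant in ("all", "up", "down"):
        mapped, count = attach_indicator(g, indicators[variant])
        logger.info("variant %s: %d indicator-1 genes on the interactome",
                    variant, count)
        out.solutions[variant] = greedy_max_subnetwork(g, mapped, k=k, variant=variant)
    return out
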