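"""Shared independent oracles used by the test-suite (kept free of any
imports from the implementation paths they check)."""

from itertools import combinations

import networkx as nx
import numpy as np


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from the textbook definition:
    q(i) = min_{j >= i} p(j) * m / j over the sorted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top
        running = min(running, p[idx] * m / i)
        q[idx] = running
    return q


def naive_all_connected_best(g: nx.Graph, ind: dict, k: int):
    """Brute-force enumeration of every connected node subset with at
    most k indicator-0 members; best by (de_count desc, fewer exceptions,
    lexicographically smallest node tuple)."""
    nodes = sorted(g.nodes)
    best_key, best_set = None, set()
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            s = set(subset)
            exc = {v for v in s if ind[v] == 0}
            if len(exc) > k or len(s) == len(exc):
                continue
            if not nx.is_connected(g.subgraph(s)):
                continue
            key = (-(len(s) - len(exc)), len(exc), tuple(sorted(s)))
            if best_key is None or key < best_key:
                best_key, best_set = key, s
    return best_key, best_set
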