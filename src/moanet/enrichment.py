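"""Over-representation analysis of subnetwork genes against GMT collections.

The test is the upper-tail hypergeometric (one-sided Fisher): given a
universe of N genes of which K belong to a pathway, and a query of n
genes with k of them in the pathway, p = sum_{i>=k} C(K,i) C(N-K,n-i) /
C(N,n). FDR is Benjamini-Hochberg per collection. The retained rows are
then filtered by FDR, a cancer-keyword rule and a minimum overlap size.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "ora",
    "filter_pathways",
    "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = ("signal", "apoptosis", "cell cycle")


class GmtError(ValueError):
    """Raised on malformed GMT input."""


@dataclass
class GeneSetCollection:
    """Named gene sets from one pathway database.

    Term keys are namespaced ``db::term``; member genes are uppercased
    and deduplicated.
    """

    source_db: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise GmtError(f"empty gene set for term {term!r}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def term_name(self, term: str) -> str:
        return term.split("::", 1)[1] if "::" in term else term


def read_gmt(path, source_db: str | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (term, description, genes...)."""
    path = Path(path)
    db = source_db or path.stem
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtError(f"{path}:{lineno}: term has no genes")
            term = f"{db}::{parts[0].strip()}"
            if term in sets:
                raise GmtError(f"{path}:{lineno}: duplicate term {parts[0]!r}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not genes:
                raise GmtError(f"{path}:{lineno}: term has no genes")
            sets[term] = genes
    return GeneSetCollection(source_db=db, sets=sets)


def ora(query: set[str], coll: GeneSetCollection,
        universe: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set.

    The default universe is every gene annotated anywhere in the
    collection; query genes outside the universe are dropped (with the
    count logged). Returns one row per term with columns term, db, k,
    K_term, n_query, N, p_value, fdr and overlap_genes (a frozenset),
    sorted by (p_value, term).
    """
    query = {str(g).upper() for g in query}
    uni = set(universe) if universe is not None else set(coll.universe)
    if not uni:
        raise ValueError("universe is empty")
    dropped = len(query - uni)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    query &= uni
    if not query:
        raise ValueError("query empty after intersecting with the universe")
    n = len(query)
    N = len(uni)
    rows = []
    for term, genes in sorted(coll.sets.items()):
        term_genes = genes & uni
        overlap = frozenset(query & term_genes)
        k, K = len(overlap), len(term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "db": coll.source_db, "k": k, "K_term": K,
                     "n_query": n, "N": N, "p_value": min(max(p, 0.0), 1.0),
                     "overlap_genes": overlap})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    return df[["term", "db", "k", "K_term", "n_query", "N",
               "p_value", "fdr", "overlap_genes"]]


def _collapse_ws(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip().casefold()


def filter_pathways(rows: pd.DataFrame, fdr_max: float = 0.05,
                    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
                    min_genes: int = 3) -> pd.DataFrame:
    """Keep significant cancer-keyword pathways with enough overlap genes.

    A row survives iff fdr < fdr_max, at least one keyword is a
    case-insensitive substring of the term display name (internal
    whitespace collapsed on both sides), and k >= min_genes.
    """
    if rows.empty:
        return rows
    kw = [_collapse_ws(k) for k in keywords]

    def name_matches(term: str) -> bool:
        name = _collapse_ws(term.split("::", 1)[-1])
        return any(k in name for k in kw)

    keep = (
        (rows["fdr"] < fdr_max)
        & (rows["k"] >= min_genes)
        & rows["term"].map(name_matches)
    )
    out = rows.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("no pathways survive the FDR/keyword/size filter")
    return out
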