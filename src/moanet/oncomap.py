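"""Projection of enriched pathway terms onto canonical oncogenic pathways.

The canonical set is the ten TCGA Pan-Cancer oncogenic signalling
pathways (cell cycle, Hippo, Myc, Notch, NRF2, PI3K/Akt, RTK-RAS-MAPK,
TGF-beta, p53, Wnt/beta-catenin) plus immune signalling as an eleventh
group. A shipped, user-editable synonym dictionary maps term display
names to canonical ids by case-insensitive pattern matching; each
pattern row carries the carcinogenesis process categories it supports
(cell cycle/proliferation/apoptosis, metastasis/invasion, angiogenesis).
Direction (up/down/both/unresolved) comes from the significance of the
term in the enrichments of the up- and down-regulated subnetworks. When
a term maps to several categories all of them are reported together with
the supporting overlap genes, so a user can arbitrate; the tool never
invents a functional call of its own.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CanonicalDictionary",
    "ProcessAssignment",
    "load_canonical_dictionary",
    "match_canonical",
    "assign_direction",
    "assign_process",
    "map_pathways",
    "PROCESS_CATEGORIES",
]

PROCESS_CATEGORIES = (
    "cell cycle/proliferation/apoptosis",
    "metastasis/invasion",
    "angiogenesis",
)


@dataclass(frozen=True)
class DictEntry:
    canonical_id: str
    pattern: str  # case-insensitive regex; plain substrings are valid regexes
    categories: tuple[str, ...]


@dataclass
class CanonicalDictionary:
    """Synonym patterns for the canonical oncogenic pathways."""

    entries: tuple[DictEntry, ...]

    def __post_init__(self) -> None:
        ids = {e.canonical_id for e in self.entries}
        for cid in ids:
            if not any(e.pattern for e in self.entries if e.canonical_id == cid):
                raise ValueError(f"canonical id {cid!r} has no pattern")
        for e in self.entries:
            bad = set(e.categories) - set(PROCESS_CATEGORIES)
            if bad:
                raise ValueError(f"unknown process categories {sorted(bad)}")

    @property
    def canonical_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.canonical_id not in seen:
                seen.append(e.canonical_id)
        return tuple(seen)


def load_canonical_dictionary(path=None) -> CanonicalDictionary:
    """Load the canonical-pathway dictionary (the shipped one by default).

    The TSV columns are canonical_id, pattern, categories (semicolon
    separated); patterns are case-insensitive regexes matched against the
    whitespace-collapsed term display name.
    """
    if path is None:
        source = resources.files("moanet").joinpath("data/canonical_pathways.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        if not str(row["pattern"]).strip():
            raise ValueError("empty pattern in canonical dictionary")
        cats = tuple(c.strip() for c in str(row["categories"]).split(";") if c.strip())
        entries.append(DictEntry(canonical_id=str(row["canonical_id"]),
                                 pattern=str(row["pattern"]),
                                 categories=cats))
    return CanonicalDictionary(entries=tuple(entries))


def _display_name(term: str) -> str:
    name = term.split("::", 1)[-1]
    return re.sub(r"\s+", " ", name).strip()


def match_canonical(term: str, dictionary: CanonicalDictionary) -> list[str]:
    """Canonical ids whose synonym patterns match the term display name.

    Multiple matches are allowed; an empty list flags the term for manual
    review (it is reported as unmatched, never dropped silently).
    """
    name = _display_name(term)
    hits: list[str] = []
    for entry in dictionary.entries:
        if re.search(entry.pattern, name, flags=re.IGNORECASE):
            if entry.canonical_id not in hits:
                hits.append(entry.canonical_id)
    return hits


def _significant_terms(rows: pd.DataFrame | None, fdr_max: float) -> set[str]:
    if rows is None or rows.empty:
        return set()
    return set(rows.loc[rows["fdr"] < fdr_max, "term"])


def assign_direction(term: str, up_rows: pd.DataFrame | None,
                     down_rows: pd.DataFrame | None,
                     fdr_max: float = 0.05) -> str:
    """Direction of a pathway from the directional subnetwork enrichments.

    ``up`` if significant only in the up-regulated subnetwork's
    enrichment, ``down`` if only in the down one, ``both`` if in both and
    ``unresolved`` if in neither (i.e. significant only for the combined
    subnetwork).
    """
    in_up = term in _significant_terms(up_rows, fdr_max)
    in_down = term in _significant_terms(down_rows, fdr_max)
    if in_up and in_down:
        return "both"
    if in_up:
        return "up"
    if in_down:
        return "down"
    return "unresolved"


@dataclass(frozen=True)
class ProcessAssignment:
    """One pathway term mapped onto canonical pathways and processes."""

    term: str
    canonical_ids: tuple[str, ...]
    categories: tuple[str, ...]
    direction: str
    supporting_genes: tuple[str, ...]


def assign_process(term: str, canonical_ids: list[str],
                   dictionary: CanonicalDictionary,
                   overlap_genes: frozenset[str] | set[str] = frozenset(),
                   direction: str = "unresolved") -> ProcessAssignment:
    """Process categories for a canonically matched term.

    Categories are the union over the matched pattern rows; when a
    canonical pathway allows several, all are reported with the term's
    overlap genes attached as supporting evidence.
    """
    if not canonical_ids:
        raise ValueError("assign_process requires a non-empty canonical match")
    name = _display_name(term)
    cats: list[str] = []
    for entry in dictionary.entries:
        if entry.canonical_id in canonical_ids and \
                re.search(entry.pattern, name, flags=re.IGNORECASE):
            for c in entry.categories:
                if c not in cats:
                    cats.append(c)
    return ProcessAssignment(term=term, canonical_ids=tuple(canonical_ids),
                             categories=tuple(cats), direction=direction,
                             supporting_genes=tuple(sorted(overlap_genes)))


def map_pathways(representatives: pd.DataFrame,
                 up_rows: pd.DataFrame | None,
                 down_rows: pd.DataFrame | None,
                 dictionary: CanonicalDictionary | None = None,
                 fdr_max: float = 0.05) -> pd.DataFrame:
    """Full oncomap table for the retained pathway terms.

    Every retained term appears exactly once: either mapped (with its
    canonical ids, categories, direction and supporting genes) or
    explicitly flagged unmatched. Returns a DataFrame with columns term,
    canonical, category, direction, genes, matched.
    """
    if dictionary is None:
        dictionary = load_canonical_dictionary()
    rows = []
    for _, row in representatives.iterrows():
        term = row["term"]
        hits = match_canonical(term, dictionary)
        direction = assign_direction(term, up_rows, down_rows, fdr_max=fdr_max)
        genes = row.get("overlap_genes", frozenset())
        if hits:
            pa = assign_process(term, hits, dictionary, genes, direction)
            rows.append({"term": term, "canonical": ";".join(pa.canonical_ids),
                         "category": ";".join(pa.categories),
                         "direction": pa.direction,
                         "genes": ",".join(pa.supporting_genes),
                         "matched": True})
        else:
            rows.append({"term": term, "canonical": "", "category": "unmatched",
                         "direction": direction,
                         "genes": ",".join(sorted(genes)), "matched": False})
    return pd.DataFrame(rows, columns=["term", "canonical", "category",
                                       "direction", "genes", "matched"])
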