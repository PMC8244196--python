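"""Seeded synthetic inputs with known ground truth.

The generator emulates the shape of the pipeline's real inputs at desk
scale: a scale-free (preferential-attachment) interactome, a planted
connected module whose members are differentially expressed (with a
budgeted number of indicator-0 "exception" members), a two-group log2
expression matrix with Gaussian noise and a mean-shift treatment effect
on the module, and a GMT collection containing one true pathway holding
the module plus decoy terms engineered to realize exact pairwise Jaccard
overlaps with it. All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import CONTROL, TREATMENT, ExpressionMatrix, SampleSheet
from .interactome import write_edge_list

__all__ = [
    "FixtureTruth",
    "simulate_interactome",
    "plant_module",
    "simulate_expression",
    "simulate_gmt",
    "write_fixture_bundle",
    "DEFAULTS",
]

#: study conditions for the default end-to-end fixture
DEFAULTS = dict(n_nodes=300, attach=2, module_size=15, n_exceptions=3,
                delta=2.0, sigma=0.5, n_ctrl=5, n_trt=5)

# the planted term name carries both the keyword-filter token ("signaling")
# and a canonical synonym ("NRF2") so the oncomap stage can place it
TRUE_TERM = "TRUE_NRF2_SIGNALING_PATHWAY"
TRUE_TERM_CANONICAL = "NRF2"
TRUE_TERM_CATEGORY = "cell cycle/proliferation/apoptosis"
NEGATIVE_TERM = "NEGATIVE_CONTROL_SIGNALING"


@dataclass
class FixtureTruth:
    """Ground truth of a planted fixture."""

    seed: int
    planted_module: tuple[str, ...] = ()
    planted_exceptions: tuple[str, ...] = ()
    planted_de_genes: dict[str, int] = field(default_factory=dict)  # gene -> sign
    planted_terms: dict[str, float] = field(default_factory=dict)  # term -> J to true term

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_module": sorted(self.planted_module),
            "planted_exceptions": sorted(self.planted_exceptions),
            "planted_de_genes": {g: self.planted_de_genes[g]
                                 for g in sorted(self.planted_de_genes)},
            "planted_terms": {t: self.planted_terms[t]
                              for t in sorted(self.planted_terms)},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "FixtureTruth":
        payload = json.loads(Path(path).read_text())
        return cls(seed=payload["seed"],
                   planted_module=tuple(payload["planted_module"]),
                   planted_exceptions=tuple(payload["planted_exceptions"]),
                   planted_de_genes={g: int(s) for g, s in
                                     payload["planted_de_genes"].items()},
                   planted_terms={t: float(j) for t, j in
                                  payload["planted_terms"].items()})


def _gene_label(i: int) -> str:
    return f"G{i + 1:04d}"


def simulate_interactome(n: int, attach: int, seed: int) -> nx.Graph:
    """Scale-free interactome via Barabasi-Albert preferential attachment.

    Exactly ``n`` nodes labelled G0001.., connected by construction.
    Requires ``n > attach >= 1``.
    """
    if attach < 1 or n <= attach:
        raise ValueError(f"need n > attach >= 1, got n={n}, attach={attach}")
    g = nx.barabasi_albert_graph(n, attach, seed=int(seed))
    return nx.relabel_nodes(g, {i: _gene_label(i) for i in g.nodes})


def plant_module(g: nx.Graph, size: int, n_exceptions: int, seed: int,
                 ) -> FixtureTruth:
    """Plant a random connected module with a budget of exception members.

    The module grows by seeded BFS from a random start node. Exception
    members (indicator 0) are chosen among non-articulation points of the
    remaining module subgraph, so the differentially expressed part stays
    connected and the module is recoverable with exception budget
    K = ``n_exceptions``.
    """
    if size > g.number_of_nodes():
        raise ValueError("module size exceeds graph size")
    if n_exceptions >= size:
        raise ValueError("n_exceptions must be smaller than the module size")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module = [start]
    member = {start}
    frontier = sorted(set(g.neighbors(start)))
    while len(module) < size and frontier:
        nxt = frontier[int(rng.integers(len(frontier)))]
        module.append(nxt)
        member.add(nxt)
        frontier = sorted({w for u in member for w in g.neighbors(u)} - member)
    if len(module) < size:
        raise ValueError("graph too small to grow the requested module")
    sub = g.subgraph(member)
    exceptions: set[str] = set()
    candidates = list(module)
    rng.shuffle(candidates)
    for cand in candidates:
        if len(exceptions) == n_exceptions:
            break
        remaining = member - exceptions - {cand}
        if len(remaining) < 1:
            continue
        if nx.is_connected(sub.subgraph(remaining)):
            exceptions.add(cand)
    if len(exceptions) < n_exceptions:
        raise ValueError("could not place exceptions without disconnecting "
                         "the module; try a larger module")
    de = {n: 1 for n in member - exceptions}
    return FixtureTruth(seed=int(seed), planted_module=tuple(sorted(member)),
                        planted_exceptions=tuple(sorted(exceptions)),
                        planted_de_genes=de)


def simulate_expression(g: nx.Graph, truth: FixtureTruth, delta: float = 2.0,
                        sigma: float = 0.5, n_ctrl: int = 5, n_trt: int = 5,
                        seed: int | None = None, frac_down: float = 0.0,
                        mode: str = "log2",
                        ) -> tuple[ExpressionMatrix, SampleSheet]:
    """Two-group expression matrix with a mean-shift signal on the module.

    Every gene gets a baseline mean (N(7,1) log2 units) and i.i.d.
    Gaussian noise of sd ``sigma``; the differentially expressed module
    genes get a treatment-group shift of +-``delta`` log2 units
    (``frac_down`` of them negative; signs recorded in the truth).
    Exception genes get no shift. ``mode="counts"`` exponentiates and
    Poisson-samples to yield an integer count matrix for exercising the
    count filter.
    """
    if delta == 0:
        raise ValueError("delta must be non-zero")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 1)
    genes = sorted(g.nodes)
    de_genes = sorted(truth.planted_de_genes)
    n_down = int(round(frac_down * len(de_genes)))
    down = set(rng.choice(de_genes, size=n_down, replace=False)) if n_down else set()
    for gene in de_genes:
        truth.planted_de_genes[gene] = -1 if gene in down else 1
    n_samples = n_ctrl + n_trt
    base = rng.normal(7.0, 1.0, size=len(genes))
    values = rng.normal(0.0, sigma, size=(len(genes), n_samples)) + base[:, None]
    shift = np.zeros(len(genes))
    index = {gene: i for i, gene in enumerate(genes)}
    for gene, sign in truth.planted_de_genes.items():
        shift[index[gene]] = sign * delta
    values[:, n_ctrl:] += shift[:, None]
    columns = [f"ctrl_{i + 1}" for i in range(n_ctrl)] + \
              [f"trt_{i + 1}" for i in range(n_trt)]
    sheet = SampleSheet(control=tuple(columns[:n_ctrl]),
                        treatment=tuple(columns[n_ctrl:]))
    df = pd.DataFrame(values, index=genes, columns=columns)
    if mode == "log2":
        return ExpressionMatrix(data=df, scale="log2"), sheet
    if mode == "counts":
        lam = np.power(2.0, df.to_numpy()) - 1.0
        counts = rng.poisson(np.clip(lam, 0.0, None))
        return ExpressionMatrix(data=pd.DataFrame(counts, index=genes,
                                                  columns=columns),
                                scale="counts"), sheet
    raise ValueError(f"unknown mode {mode!r}")


def _feasible_overlaps(a: int, b: int, j: float, window: int = 5) -> list[tuple[int, int, int]]:
    """Nearby (a, b, c) triples realizing J exactly (c shared genes)."""
    out = []
    for bb in range(max(1, b - window), b + window + 1):
        c = j * (a + bb) / (1.0 + j)
        if abs(c - round(c)) < 1e-9 and 1 <= round(c) <= min(a, bb):
            out.append((a, bb, int(round(c))))
    return out


def simulate_gmt(truth: FixtureTruth, g: nx.Graph,
                 overlap_spec: list[tuple[str, int, float]] | None = None,
                 n_random_terms: int = 3, random_term_size: int = 12,
                 seed: int | None = None) -> dict[str, frozenset[str]]:
    """GMT gene sets with engineered Jaccard overlaps to the true term.

    The true term holds all planted module genes. Each ``overlap_spec``
    entry ``(name, size, target_J)`` builds a decoy of the given size
    sharing ``c`` genes with the true term, where ``c/(a + size - c) =
    target_J`` must have an integer solution — otherwise an error lists
    feasible nearby sizes. Shared genes are drawn from the module,
    fillers from off-module genes. A known-negative term with no module
    genes and ``n_random_terms`` off-module decoys are always included;
    every name carries the keyword "signaling" so terms survive the
    keyword filter. Realized Jaccard values are recorded in the truth.
    """
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 2)
    module = sorted(truth.planted_module)
    a = len(module)
    off_pool = sorted(set(g.nodes) - set(module))
    rng.shuffle(off_pool)
    pool_iter = iter(off_pool)

    def take(n: int) -> list[str]:
        return [next(pool_iter) for _ in range(n)]

    sets: dict[str, frozenset[str]] = {TRUE_TERM: frozenset(module)}
    truth.planted_terms = {TRUE_TERM: 1.0}
    if overlap_spec is None:
        overlap_spec = [
            ("REDUNDANT_SIGNALING_A", 10, 2.0 / 3.0),   # J > 0.60: collapses
            ("CROSSTALK_SIGNALING_A", 9, 1.0 / 3.0),    # crosstalk band
            ("CROSSTALK_SIGNALING_B", 10, 0.25),        # inclusive boundary
        ]
    for name, b, j in overlap_spec:
        if not 0 <= j <= 1:
            raise ValueError(f"target Jaccard {j} outside [0, 1]")
        c = j * (a + b) / (1.0 + j)
        if abs(c - round(c)) > 1e-9 or not 1 <= round(c) <= min(a, b):
            feasible = _feasible_overlaps(a, b, j)
            raise ValueError(
                f"J={j:g} infeasible for sizes ({a}, {b}): shared count "
                f"c={c:.4g} is not an integer in [1, min(a,b)]; feasible "
                f"nearby (a, b, c): {feasible}")
        c = int(round(c))
        # shared genes drawn DE-first so the overlap persists after the
        # enrichment stage intersects terms with the recovered subnetwork
        de_first = sorted(truth.planted_de_genes) + sorted(truth.planted_exceptions)
        pick = sorted(rng.permutation(len(truth.planted_de_genes))[:c]) \
            if c <= len(truth.planted_de_genes) else range(c)
        shared = [de_first[i] for i in pick]
        members = frozenset(shared + take(b - c))
        realized = len(set(members) & set(module)) / len(set(members) | set(module))
        sets[name] = members
        truth.planted_terms[name] = realized
    sets[NEGATIVE_TERM] = frozenset(take(random_term_size))
    truth.planted_terms[NEGATIVE_TERM] = 0.0
    for i in range(n_random_terms):
        name = f"RANDOM_SIGNALING_{i + 1:02d}"
        sets[name] = frozenset(take(random_term_size))
        truth.planted_terms[name] = 0.0
    return sets


def write_fixture_bundle(outdir, seed: int, **overrides) -> FixtureTruth:
    """Write a complete pipeline input bundle under ``outdir``.

    Files: expression.tsv (log2 scale), samples.tsv, network.tsv,
    pathways.gmt, truth.json and a ready-to-run config.yaml declaring
    the scale. Parameters default to the study conditions in
    :data:`DEFAULTS`; keyword overrides adjust them.
    """
    params = dict(DEFAULTS)
    params.update(overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = simulate_interactome(params["n_nodes"], params["attach"], seed)
    truth = plant_module(g, params["module_size"], params["n_exceptions"], seed)
    matrix, sheet = simulate_expression(
        g, truth, delta=params["delta"], sigma=params["sigma"],
        n_ctrl=params["n_ctrl"], n_trt=params["n_trt"])
    sets = simulate_gmt(truth, g)

    matrix.data.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame({
        "sample_id": list(sheet.samples),
        "group": [CONTROL] * len(sheet.control) + [TREATMENT] * len(sheet.treatment),
    }).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_edge_list(g, outdir / "network.tsv")
    with open(outdir / "pathways.gmt", "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\tsynthetic\t{genes}\n")
    truth.to_json(outdir / "truth.json")
    config = {
        "expression": str(outdir / "expression.tsv"),
        "sample_sheet": str(outdir / "samples.tsv"),
        "network": str(outdir / "network.tsv"),
        "gmt": [str(outdir / "pathways.gmt")],
        "scale": "log2",
        "seed": int(seed),
    }
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth
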