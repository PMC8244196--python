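"""Pipeline orchestration: run every stage in order and record a manifest.

Stage order mirrors the analysis workflow: expression QC and moderated
differential expression -> binarization -> K-exception subnetwork
extraction (all/up/down variants) -> centrality hubs -> ORA enrichment
per variant -> redundancy collapse + crosstalk network + clustering ->
canonical oncogenic pathway / process mapping. Every stage's inputs,
outputs and parameters are echoed into ``manifest.json``; given the same
config and seed the run directory is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .centrality import compute_centrality, top_genes
from .enrichment import DEFAULT_KEYWORDS, filter_pathways, ora, read_gmt
from .expression import (binarize, collapse_probes, differential_expression,
                         filter_low_counts, log2_normalize, pca_qc,
                         read_expression, read_sample_sheet)
from .interactome import read_network
from .oncomap import load_canonical_dictionary, map_pathways
from .pathway_network import (build_crosstalk_network, cluster_pathways,
                              collapse_redundant)
from .subnetwork import extract_all_variants

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

VARIANTS = ("all", "up", "down")


@dataclass
class PipelineConfig:
    """All tunable thresholds plus input paths for one run.

    Defaults are the stringent preset (FDR 5e-3); the alternative preset
    used for noisier datasets is 1e-2.
    """

    expression: str = ""
    sample_sheet: str = ""
    network: str = ""
    network_format: str = "edge_tsv"
    gmt: tuple[str, ...] = ()
    dictionary: str | None = None
    probe_map: str | None = None
    scale: str | None = None

    fc_cutoff: float = 2.0
    fdr_cutoff: float = 5e-3
    k_exceptions: int = 5
    ora_fdr_max: float = 0.05
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    min_overlap_genes: int = 3
    redundancy_cutoff: float = 0.60
    crosstalk_cutoff: float = 0.25
    top_n: int = 5
    universe_mode: str = "collection"  # collection | interactome | measured
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if self.k_exceptions < 0:
            raise ValueError("k_exceptions must be non-negative")
        for name in ("ora_fdr_max", "redundancy_cutoff", "crosstalk_cutoff"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.universe_mode not in ("collection", "interactome", "measured"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        self.gmt = tuple(self.gmt)
        self.keywords = tuple(self.keywords)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["gmt"] = list(self.gmt)
        out["keywords"] = list(self.keywords)
        return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _serialize_overlap(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "overlap_genes" in out.columns:
        out["overlap_genes"] = out["overlap_genes"].map(
            lambda s: ",".join(sorted(s)))
    return out


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full workflow into ``outdir`` and return that path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("moanet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"package": "moanet", "version": __version__,
                      "config": config.to_dict(), "inputs": {}, "stages": []}
    try:
        return _run(config, outdir, manifest)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"stage": name, **info})


def _run(config: PipelineConfig, outdir: Path, manifest: dict) -> Path:
    for key in ("expression", "sample_sheet", "network"):
        path = getattr(config, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"stage inputs: missing {key} file {path!r}")
        manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    for p in config.gmt:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage inputs: missing GMT file {p!r}")
    manifest["inputs"]["gmt"] = [{"path": str(p), "sha256": _sha256(p)}
                                 for p in config.gmt]

    # --- expression -----------------------------------------------------
    sheet = read_sample_sheet(config.sample_sheet)
    rows = "probes" if config.probe_map else "genes"
    matrix = read_expression(config.expression, sheet, scale=config.scale, rows=rows)
    if config.probe_map:
        pm = pd.read_csv(config.probe_map, sep="\t", dtype=str)
        matrix = collapse_probes(matrix, dict(zip(pm.iloc[:, 0], pm.iloc[:, 1])))
    if matrix.scale == "counts":
        matrix = filter_low_counts(matrix, sheet)
    if matrix.scale != "log2":
        matrix = log2_normalize(matrix)
    qc = pca_qc(matrix, sheet)
    _write_tsv(qc.coordinates.rename_axis("sample_id"), outdir / "pca_qc.tsv",
               index=True)
    de = differential_expression(matrix, sheet)
    indicators = binarize(de, fc_cutoff=config.fc_cutoff,
                          fdr_cutoff=config.fdr_cutoff)
    de_out = de.copy()
    for variant in VARIANTS:
        de_out[f"indicator_{variant}"] = [indicators[variant].values[str(g)]
                                          for g in de.index]
    _write_tsv(de_out.rename_axis("gene").round(10), outdir / "de_table.tsv",
               index=True)
    _stage(manifest, "expression", genes=int(len(de)),
           pca_separated=bool(qc.separated),
           de_flagged=int(sum(indicators["all"].values.values())),
           params={"fc_cutoff": config.fc_cutoff, "fdr_cutoff": config.fdr_cutoff},
           outputs=["pca_qc.tsv", "de_table.tsv"])

    # --- interactome + subnetworks --------------------------------------
    g = read_network(config.network, format=config.network_format)
    solutions = extract_all_variants(g, de, fc_cutoff=config.fc_cutoff,
                                     fdr_cutoff=config.fdr_cutoff,
                                     k=config.k_exceptions)
    _write_tsv(solutions.summary(), outdir / "subnetwork_summary.tsv")
    for variant in VARIANTS:
        sol = solutions.solutions[variant]
        _write_tsv(pd.DataFrame(list(sol.edges), columns=["gene_a", "gene_b"]),
                   outdir / f"subnetwork_{variant}_edges.tsv")
        _write_tsv(sol.node_table(), outdir / f"subnetwork_{variant}_nodes.tsv")
    _stage(manifest, "subnetwork",
           params={"K": config.k_exceptions},
           sizes={v: len(solutions.solutions[v].nodes) for v in VARIANTS},
           outputs=["subnetwork_summary.tsv"]
           + [f"subnetwork_{v}_{kind}.tsv" for v in VARIANTS
              for kind in ("edges", "nodes")])

    # --- centrality ------------------------------------------------------
    sol_all = solutions.solutions["all"]
    if not sol_all.is_empty:
        table = compute_centrality(sol_all)
        hubs = top_genes(table, n=min(config.top_n, len(table)))
        table = table.copy()
        table["top_n_flag"] = table.index.isin(hubs)
        _write_tsv(table.rename_axis("gene").round(10), outdir / "centrality.tsv",
                   index=True)
    else:
        hubs = []
        _write_tsv(pd.DataFrame(columns=["gene", "degree", "betweenness",
                                         "rank_degree", "rank_betweenness",
                                         "composite_score", "composite_rank",
                                         "top_n_flag"]),
                   outdir / "centrality.tsv")
        logger.warning("empty all-variant subnetwork; centrality table empty")
    _stage(manifest, "centrality", top_genes=hubs,
           params={"top_n": config.top_n}, outputs=["centrality.tsv"])

    # --- enrichment ------------------------------------------------------
    collections = [read_gmt(p) for p in config.gmt]
    measured = {str(x).upper() for x in de.index}
    enrich_filtered: dict[str, pd.DataFrame] = {}
    enrich_raw: dict[str, pd.DataFrame] = {}
    for variant in VARIANTS:
        sol = solutions.solutions[variant]
        frames = []
        for coll in collections:
            if sol.is_empty:
                continue
            universe = None
            if config.universe_mode == "interactome":
                universe = set(g.nodes)
            elif config.universe_mode == "measured":
                universe = measured
            try:
                frames.append(ora(set(sol.nodes), coll, universe=universe))
            except ValueError as exc:
                logger.warning("enrichment skipped for variant %s / %s: %s",
                               variant, coll.source_db, exc)
        raw = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["term", "db", "k", "K_term", "n_query", "N",
                     "p_value", "fdr", "overlap_genes"])
        enrich_raw[variant] = raw
        filtered = filter_pathways(raw, fdr_max=config.ora_fdr_max,
                                   keywords=config.keywords,
                                   min_genes=config.min_overlap_genes)
        enrich_filtered[variant] = filtered
        _write_tsv(_serialize_overlap(raw).round(12),
                   outdir / f"enrichment_{variant}_raw.tsv")
        _write_tsv(_serialize_overlap(filtered).round(12),
                   outdir / f"enrichment_{variant}.tsv")
    _stage(manifest, "enrichment",
           params={"ora_fdr_max": config.ora_fdr_max,
                   "keywords": list(config.keywords),
                   "min_overlap_genes": config.min_overlap_genes,
                   "universe_mode": config.universe_mode},
           retained={v: int(len(enrich_filtered[v])) for v in VARIANTS},
           outputs=[f"enrichment_{v}{suffix}.tsv" for v in VARIANTS
                    for suffix in ("_raw", "")])

    # --- pathway network --------------------------------------------------
    reps, redundancy_map = collapse_redundant(
        enrich_filtered["all"], redundancy_cutoff=config.redundancy_cutoff)
    pg = build_crosstalk_network(reps, crosstalk_cutoff=config.crosstalk_cutoff,
                                 redundancy_cutoff=config.redundancy_cutoff)
    cluster_pathways(pg)
    _write_tsv(pg.edge_table().round(10), outdir / "pathway_edges.tsv")
    _write_tsv(pg.cluster_table(), outdir / "pathway_clusters.tsv")
    _write_tsv(pd.DataFrame(sorted(redundancy_map.items()),
                            columns=["term", "representative"]),
               outdir / "redundancy_map.tsv")
    _stage(manifest, "pathway_network",
           params={"redundancy_cutoff": config.redundancy_cutoff,
                   "crosstalk_cutoff": config.crosstalk_cutoff},
           representatives=int(len(reps)),
           clusters=int(len(set(pg.clusters.values()))),
           outputs=["pathway_edges.tsv", "pathway_clusters.tsv",
                    "redundancy_map.tsv"])

    # --- oncomap ----------------------------------------------------------
    dictionary = load_canonical_dictionary(config.dictionary)
    assignments = map_pathways(reps, enrich_raw["up"], enrich_raw["down"],
                               dictionary=dictionary, fdr_max=config.ora_fdr_max)
    _write_tsv(assignments, outdir / "process_assignments.tsv")
    _stage(manifest, "oncomap",
           matched=int(assignments["matched"].sum()),
           unmatched=int((~assignments["matched"]).sum()),
           outputs=["process_assignments.tsv"])

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", outdir)
    return outdir
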