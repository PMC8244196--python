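# Methods

## Scope and model

`moanet` implements a transcriptome → interactome → pathway inference
chain for compound mechanism-of-action analysis. The statistical model
has three layers: (i) a gene-level moderated two-group comparison on
log2 expression; (ii) a combinatorial optimization on the protein
interaction graph selecting the connected subgraph that concentrates
differential expression; (iii) set-overlap statistics (hypergeometric
enrichment, Jaccard similarity) that turn the subnetwork into an
interpretable map of signalling pathways and carcinogenesis processes.

## Differential expression and binarization

Inputs may be microarray intensities, RNA-seq counts or already-log2
values; the scale is an explicit tag because log-ness cannot be inferred
reliably (an all-integer matrix is assumed to be counts). Counts are
filtered to genes with non-zero values in at least two samples of either
group and transformed as log2(x+1); intensities as log2(max(x,1)). The
pseudocount/floor of 1 keeps zeros finite and maps them to 0.

The test is a moderated t: pooled per-gene variance s² with
d = n₁+n₂−2 df, a scaled-inverse-chi-square prior (d₀, s₀²) fitted by
the method of moments on z = log s² (digamma/trigamma moment equations,
trigamma inverted by Newton iteration), posterior variance
(d₀s₀² + d·s²)/(d₀+d) and d+d₀ reference df. Two boundary cases:

* **No excess variance** (the spread of log s² does not exceed
  chi-square sampling noise): the gene variances are statistically
  indistinguishable, which is the d₀ → ∞ limit — full shrinkage to s₀²
  and a normal reference. This case occurs routinely on clean synthetic
  data with a common noise sd.
* **Moment estimation impossible** (fewer than three genes with positive
  variance): fall back to the ordinary pooled t (d₀ = 0). A gene that is
  constant with equal group means reports t = 0, p = 1 rather than an
  error.

The implementation is cross-checked against Bioconductor limma
(`lmFit`/`eBayes` via Rscript) on a fixture with heterogeneous gene
variances: t statistics agree to 1e-4 relative, and the estimated prior
df matches `fitFDist` to 1e-3. FDR is Benjamini–Hochberg (statsmodels),
verified against the step-up definition on random p-vectors.

Binarization: indicator 1 ⇔ |log2FC| ≥ log2(FC cutoff) and
FDR < cutoff. Defaults FC = 2 (linear) and FDR = 5×10⁻³, with 10⁻² as
the shipped lenient preset; both appear in practice depending on how
noisy a dataset is. Up/down variants additionally require the fold
change sign, so |up| + |down| = |all| by construction.

## PCA screen

An advisory (never blocking) check that control and treatment samples
separate: PCA on the 500 highest-variance genes; "separated" iff the
distance between the two group centroids in (PC1, PC2) exceeds the
larger within-group mean distance to the own centroid. This
operationalizes a visual QC step deterministically; it is a coarse
heuristic and deliberately reported rather than enforced.

## K-exception subnetwork extraction

Objective: a connected induced subgraph maximizing the count of
indicator-1 nodes with at most K indicator-0 exception nodes (default
K = 5). Exceptions let a solution pass through non-responsive hub
proteins. Unmeasured interactome genes default to indicator 0.

The greedy solver grows one candidate per indicator-1 seed
(lexicographic order): all adjacent indicator-1 nodes are absorbed
unconditionally; when none remain and budget is left, the indicator-0
neighbour unlocking the most indicator-1 nodes along indicator-1-only
paths is admitted (ties lexicographic; gain-0 neighbours never). The
best candidate wins by (DE count, fewer exceptions, lexicographically
smallest node list); results are locally maximal and byte-deterministic.

The exact solver exploits that any optimal solution is a connected
component of the subgraph induced by the indicator-1 nodes plus some
exception subset E (|E| ≤ K); enumerating exception subsets is feasible
on instances up to ~20 nodes and is itself verified against brute-force
enumeration of *all* connected node subsets on ≤ 12 nodes. On 200 random
instances (6–15 nodes, edge density 0.3, 30% positives, K ∈ {0,1,2})
the greedy attains the exact optimum in ≈ 97% of cases and > 98% of the
optimal DE count on average; DE count is non-decreasing in K.

## Centrality

Degree and betweenness are computed on the subnetwork, not the full
interactome. Betweenness is Brandes' algorithm (networkx), raw scores
over unordered pairs with endpoints excluded and fractional credit over
equal-length geodesics; verified against naive all-geodesic counting and
closed forms (path centre 1; star centre C(4,2) = 6; 4-cycle nodes 0.5).
The published analyses do not state how degree and betweenness combine
into a "top 5"; the symmetric, scale-free choice here is the mean of the
two descending ranks (ties share mean ranks; final ties lexicographic),
and both per-metric rankings are emitted so either reading can be
reproduced.

## Enrichment

Upper-tail hypergeometric (one-sided Fisher) per term:
p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), exact via `scipy.stats.hypergeom`
and verified against exhaustive draw enumeration for all instances with
N ≤ 12. The default universe is every gene annotated in the loaded
collection (enrichR-like); interactome or measured-gene universes are
selectable. BH runs per collection, mirroring per-library statistics of
popular enrichment servers. Filters: FDR < 0.05, case-insensitive
substring keyword match ("signal", "apoptosis", "cell cycle";
whitespace collapsed) on the term display name, and ≥ 3 overlap genes.
The keyword list is user-editable; no further "cancer-unrelated"
screening is applied beyond it.

## Pathway network

Similarity is the Jaccard index of the **enriched** gene sets — the
subnetwork∩pathway overlaps, not the full database sets. Boundary
conventions: redundancy is strict (J > 0.60), crosstalk inclusive
(J ≥ 0.25, i.e. "at least 25% common genes"). Redundancy components are
collapsed before edge construction (collapse-first; the order is
switchable), keeping per component the representative with smallest FDR,
then largest overlap, then lexicographic name — a deterministic stand-in
for manual prioritization. Clustering is greedy Clauset–Newman–Moore
modularity on the unweighted crosstalk graph (a weighted flag exists);
isolated terms become singletons, and cluster ids are assigned in order
of each cluster's smallest member for determinism. Limitation: greedy
agglomeration provably misses the global modularity optimum on
structure-less graphs (e.g. long paths or cycles — 0.26 vs 0.30 on a
6-path); on community-structured graphs (disjoint cliques, bridged
cliques, stars) it matches exhaustive maximization over all partitions,
which is the regime pathway networks occupy.

## Oncomap

The canonical set is the ten TCGA Pan-Cancer oncogenic signalling
pathways plus immune signalling. Matching uses a shipped, editable TSV
dictionary of case-insensitive regex synonyms (plain substrings except
where a word boundary is required — "EGFR" must not fire inside
"VEGFR2"); each pattern row carries its process categories, so e.g.
VEGF terms map to angiogenesis while MAPK terms map to
proliferation/apoptosis under the same canonical id. Direction is up /
down / both / unresolved according to the term's significance in the
enrichments of the up- and down-regulated subnetworks. The human
arbitration step that a curated analysis would do with protein-function
lookups is deliberately replaced by reporting: all matched categories
and the supporting overlap genes are emitted, unmatched terms are
flagged for review, and the tool never invents a functional call.

## Synthetic data

The generator emulates the study conditions end-to-end: a
Barabási–Albert scale-free interactome (default n = 300, attachment 2),
a planted connected module of 15 genes grown by seeded BFS with 3
exception members chosen among non-articulation points (so the DE part
stays connected and the module is recoverable with budget K = 3), log2
expression for 5 control + 5 treatment samples with per-gene baselines
N(7,1), noise sd σ = 0.5, and a treatment shift of ±δ = 2 log2 units on
the DE module genes (all + by default; a fraction can be flipped). With
these values the expected |t| ≈ δ/(σ√(2/5)) ≈ 6.3, placing planted
genes well past the FC ≥ 2 / FDR cutoffs while null genes stay
calibrated (empirical type-I error 0.05 ± 0.02 at α = 0.05 on 2000 null
genes). A counts mode exponentiates and Poisson-samples to exercise the
count filter. The GMT generator builds one true term containing the
module and decoys engineered by set surgery to hit exact target Jaccard
values c/(a+b−c) = J (integer-infeasible requests fail with feasible
alternatives listed); decoy overlaps are drawn DE-genes-first so the
engineered bands survive intersection with the recovered subnetwork,
and all names carry "signaling" so terms face the keyword filter on
equal footing. Not modelled: probe-level microarray artifacts, RNA-seq
overdispersion, correlated noise, library-size effects — so passing
tests demonstrate algorithmic correctness under the stated model, not
robustness to platform-specific noise.

Problem sizes in the test-suite and validation script (200 solver
instances of ≤ 15 nodes, enumeration oracles at N ≤ 12, a 300-gene
end-to-end study) were chosen so each oracle comparison is exhaustive or
near-exhaustive while the whole suite runs in seconds.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeds; graph
iteration is over sorted nodes; ties break lexicographically everywhere;
TSV floats are rounded (10–12 decimals) before writing, and rerunning a
pipeline with the same config + seed reproduces every output file
byte-for-byte (the manifest stores the config and input SHA-256s and
suffices to replay a run). The trigamma inverse uses Newton iteration
with asymptotic guards at both ends; hypergeometric tails are clipped to
[0, 1]; betweenness comparisons use 1e-9 absolute tolerance and the
moment-based d₀ is compared to limma at 1e-3 relative.

## Known limitations

* Identifier mapping beyond case-folding (probes ↔ symbols ↔ database
  namespaces) is the user's responsibility.
* Single-factor two-group designs only; no batch correction, paired
  designs or RNA-seq normalization beyond the count filter.
* The greedy subnetwork solver is a heuristic; optimality is certified
  only on oracle-sized instances.
* Enrichment-based direction calls inherit the usual caveat that
  pathway membership of up-regulated genes does not by itself establish
  pathway activation.
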