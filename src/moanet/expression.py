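"""Expression input handling and moderated differential expression.

This module covers the transcriptome side of the pipeline: reading a
genes-x-samples TSV, collapsing probes to genes, the RNA-seq low-count
filter, log2 normalization, a PCA sanity screen of the control/treatment
separation, an empirical-Bayes moderated two-group t-test and
Benjamini-Hochberg FDR, and the binarization of genes into 0/1
differential-expression indicators that drive the subnetwork search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATMENT = "treatment"

__all__ = [
    "SampleSheet",
    "ExpressionMatrix",
    "IndicatorVector",
    "PCAReport",
    "read_sample_sheet",
    "read_expression",
    "collapse_probes",
    "filter_low_counts",
    "log2_normalize",
    "pca_qc",
    "differential_expression",
    "binarize",
]


class ExpressionError(ValueError):
    """Raised on malformed expression inputs."""


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of sample ids to the control and treatment groups.

    At least two samples per group are required (three or more are
    recommended for a stable variance estimate).
    """

    control: tuple[str, ...]
    treatment: tuple[str, ...]

    def __post_init__(self) -> None:
        all_ids = list(self.control) + list(self.treatment)
        if len(set(all_ids)) != len(all_ids):
            raise ExpressionError("sample ids must be unique across groups")
        for name, grp in ((CONTROL, self.control), (TREATMENT, self.treatment)):
            if len(grp) < 2:
                raise ExpressionError(f"need at least 2 {name} samples, got {len(grp)}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.control) + tuple(self.treatment)

    def group_of(self, sample: str) -> str:
        if sample in self.control:
            return CONTROL
        if sample in self.treatment:
            return TREATMENT
        raise KeyError(sample)


def read_sample_sheet(path) -> SampleSheet:
    """Read a two-column TSV (sample_id, group) into a :class:`SampleSheet`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ExpressionError(f"sample sheet must have columns {sorted(required)}")
    bad = set(df["group"]) - {CONTROL, TREATMENT}
    if bad:
        raise ExpressionError(f"unknown group labels: {sorted(bad)}")
    ctrl = tuple(df.loc[df["group"] == CONTROL, "sample_id"])
    trt = tuple(df.loc[df["group"] == TREATMENT, "sample_id"])
    return SampleSheet(control=ctrl, treatment=trt)


@dataclass
class ExpressionMatrix:
    """Rows-x-samples expression values with an explicit scale tag.

    ``scale`` is one of ``counts`` (non-negative integers), ``intensity``
    (non-negative reals, linear scale) or ``log2``.
    """

    data: pd.DataFrame
    scale: str
    rows: str = "genes"  # or "probes"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "intensity", "log2"):
            raise ExpressionError(f"unknown scale {self.scale!r}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ExpressionError(f"duplicate sample columns: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ExpressionError("expression values must be finite")
        if self.scale == "counts":
            if (values < 0).any() or not np.allclose(values, np.round(values)):
                raise ExpressionError("counts scale requires non-negative integers")
        if self.rows == "genes" and self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate gene row ids: {dups[:5]}")


def read_expression(matrix_path, sheet: SampleSheet, scale: str | None = None,
                    rows: str = "genes") -> ExpressionMatrix:
    """Read an expression TSV and restrict/order columns to the sample sheet.

    The first column holds row ids; the header row holds sample ids. When
    ``scale`` is not given it is inferred: an all-integer matrix is taken
    to be counts, anything else linear intensities (a log2 matrix must be
    declared explicitly).
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    missing = [s for s in sheet.samples if s not in df.columns]
    if missing:
        raise ExpressionError(f"samples missing from {matrix_path}: {missing}")
    df = df[list(sheet.samples)]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ExpressionError(f"non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    if scale is None:
        values = df.to_numpy(dtype=float)
        scale = "counts" if np.allclose(values, np.round(values)) and (values >= 0).all() \
            else "intensity"
        logger.info("inferred scale=%s for %s", scale, matrix_path)
    return ExpressionMatrix(data=df, scale=scale, rows=rows)


def collapse_probes(m: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene.

    For each gene the retained probe is the one with the largest mean
    expression across all samples; ties break to the lexicographically
    smallest probe id. Probes absent from ``probe_map`` are dropped.
    """
    if not probe_map:
        raise ExpressionError("probe_map is empty")
    df = m.data
    mapped = df.loc[[p for p in df.index if p in probe_map]]
    if mapped.empty:
        raise ExpressionError("no probes matched the probe map")
    meta = pd.DataFrame({
        "probe": mapped.index,
        "gene": [probe_map[p] for p in mapped.index],
        "mean": mapped.mean(axis=1).to_numpy(),
    })
    meta = meta.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    keep = meta.drop_duplicates("gene", keep="first")
    out = mapped.loc[keep["probe"]].copy()
    out.index = keep["gene"].to_numpy()
    out = out.sort_index()
    return ExpressionMatrix(data=out, scale=m.scale, rows="genes")


def filter_low_counts(m: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Keep genes with non-zero counts in at least two samples of either group."""
    if m.scale != "counts":
        raise ExpressionError("filter_low_counts requires a counts matrix")
    ctrl = (m.data[list(sheet.control)] > 0).sum(axis=1)
    trt = (m.data[list(sheet.treatment)] > 0).sum(axis=1)
    keep = (ctrl >= 2) | (trt >= 2)
    logger.info("low-count filter kept %d/%d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(data=m.data.loc[keep].copy(), scale="counts", rows=m.rows)


def log2_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform counts (log2(x+1)) or intensities (log2(max(x, 1)))."""
    if m.scale == "log2":
        warnings.warn("matrix already on log2 scale; returning unchanged")
        return m
    if m.scale == "counts":
        out = np.log2(m.data.astype(float) + 1.0)
    else:
        out = np.log2(m.data.astype(float).clip(lower=1.0))
    return ExpressionMatrix(data=out, scale="log2", rows=m.rows)


@dataclass
class PCAReport:
    """PC1/PC2 coordinates per sample plus an advisory separation flag."""

    coordinates: pd.DataFrame  # index sample_id, columns PC1, PC2, group
    separated: bool
    explained_variance_ratio: tuple[float, float]


def pca_qc(m: ExpressionMatrix, sheet: SampleSheet, n_top_genes: int = 500) -> PCAReport:
    """PCA screen of control-vs-treatment separation.

    Samples are projected onto the first two principal components of the
    ``n_top_genes`` highest-variance genes. The groups are called
    separated when the distance between the two group centroids exceeds
    the larger of the two within-group mean distances to the own centroid.
    The flag is advisory and never blocks the pipeline.
    """
    if m.scale != "log2":
        raise ExpressionError("pca_qc expects log2-scale data")
    if len(sheet.samples) < 3:
        raise ExpressionError("pca_qc needs at least 3 samples")
    variances = m.data.var(axis=1)
    top = variances.sort_values(ascending=False).index[:n_top_genes]
    X = m.data.loc[top, list(sheet.samples)].to_numpy(dtype=float).T  # samples x genes
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    if n_comp < 2:  # degenerate: pad a zero second component
        coords = np.column_stack([coords, np.zeros(len(coords))])
    df = pd.DataFrame(coords[:, :2], index=list(sheet.samples), columns=["PC1", "PC2"])
    df["group"] = [sheet.group_of(s) for s in df.index]
    cen_c = df.loc[df["group"] == CONTROL, ["PC1", "PC2"]].mean().to_numpy()
    cen_t = df.loc[df["group"] == TREATMENT, ["PC1", "PC2"]].mean().to_numpy()
    between = float(np.linalg.norm(cen_c - cen_t))
    within = []
    for grp, cen in ((CONTROL, cen_c), (TREATMENT, cen_t)):
        pts = df.loc[df["group"] == grp, ["PC1", "PC2"]].to_numpy()
        within.append(float(np.mean(np.linalg.norm(pts - cen, axis=1))))
    evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    if len(evr) < 2:
        evr = (evr[0], 0.0) if evr else (0.0, 0.0)
    return PCAReport(coordinates=df, separated=between > max(within),
                     explained_variance_ratio=evr)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-F prior to sample variances.

    Works on z = log(s^2): E[z] and Var[z] identify the prior degrees of
    freedom d0 and prior variance s0^2 via digamma/trigamma moments.
    When the log variances show no excess spread beyond the chi-square
    sampling noise (excess variance <= 0) the gene variances are
    indistinguishable, which is the d0 = +inf boundary: full shrinkage to
    s0^2 = exp(mean(e)). Raises ``FloatingPointError`` when fewer than 3
    genes carry a positive sample variance.
    """
    ok = s2 > 0
    if ok.sum() < 3:
        raise FloatingPointError("too few positive sample variances")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def differential_expression(m: ExpressionMatrix, sheet: SampleSheet,
                            prior_df: float | None = None) -> pd.DataFrame:
    """Moderated two-group differential expression on a log2 matrix.

    Per gene: ``log2fc`` = mean(treatment) - mean(control); the pooled
    sample variance is shrunk towards a prior ``s0^2`` estimated by the
    method of moments on the log sample variances, giving the posterior
    variance ``(d0*s0^2 + d*s^2) / (d0 + d)``; the moderated t has
    ``d + d0`` degrees of freedom. Homogeneous gene variances give the
    d0 = +inf boundary (full shrinkage, normal reference distribution);
    when moment estimation fails outright (fewer than 3 genes with
    positive variance) the ordinary pooled-variance t (``d0 = 0``) is
    used. P-values are two-sided; FDR is Benjamini-Hochberg over all
    tested genes.

    ``prior_df`` forces d0 (0 recovers the ordinary t exactly).

    Returns a DataFrame indexed by gene with columns log2fc, t_stat,
    p_value, fdr.
    """
    if m.scale != "log2":
        raise ExpressionError("differential_expression expects log2-scale data")
    ctrl = m.data[list(sheet.control)].to_numpy(dtype=float)
    trt = m.data[list(sheet.treatment)].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], trt.shape[1]
    d = n1 + n2 - 2
    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    var1 = ctrl.var(axis=1, ddof=1)
    var2 = trt.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / d

    if prior_df is None:
        try:
            d0, s0sq = _fit_f_dist(s2, d)
        except FloatingPointError as exc:
            logger.warning("variance moment estimation failed (%s); "
                           "falling back to ordinary pooled t", exc)
            d0, s0sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0sq = _fit_f_dist(s2, d)[1] if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    # zero posterior variance and zero fc: no evidence either way
    t = np.where((se == 0) & (log2fc == 0), 0.0, t)
    df_total = d + d0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    if np.all(s2 == 0):
        warnings.warn("all genes have zero within-group variance")
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t, "p_value": p, "fdr": fdr},
        index=m.data.index.copy(),
    )


@dataclass(frozen=True)
class IndicatorVector:
    """Binary differential-expression labels consumed by the subnetwork solver."""

    values: dict[str, int] = field(repr=False)
    variant: str = "all"  # all | up | down
    fc_cutoff: float = 2.0
    fdr_cutoff: float = 5e-3

    def __post_init__(self) -> None:
        if self.variant not in ("all", "up", "down"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def positives(self) -> set[str]:
        return {g for g, v in self.values.items() if v == 1}


def binarize(de: pd.DataFrame, fc_cutoff: float = 2.0,
             fdr_cutoff: float = 5e-3) -> dict[str, IndicatorVector]:
    """Binarize a DE table into all/up/down indicator vectors.

    A gene is flagged in the ``all`` variant iff |log2fc| >= log2(fc_cutoff)
    and fdr < fdr_cutoff; ``up`` and ``down`` additionally require the sign
    of the fold change. ``fc_cutoff`` is a linear fold change (default 2).
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1 (linear fold change)")
    if not 0 < fdr_cutoff < 1:
        raise ValueError("fdr_cutoff must lie in (0, 1)")
    lfc_min = np.log2(fc_cutoff)
    sig = (de["log2fc"].abs() >= lfc_min) & (de["fdr"] < fdr_cutoff)
    out = {}
    for variant, mask in (
        ("all", sig),
        ("up", sig & (de["log2fc"] > 0)),
        ("down", sig & (de["log2fc"] < 0)),
    ):
        values = {str(g): int(v) for g, v in zip(de.index, mask.astype(int))}
        out[variant] = IndicatorVector(values=values, variant=variant,
                                       fc_cutoff=fc_cutoff, fdr_cutoff=fdr_cutoff)
    return out
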