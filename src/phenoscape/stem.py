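"""scRNA-seq QC, normalization, gene-program scoring and the stem-cell index.

The workflow mirrors standard droplet/SPLiT-style preprocessing: hard QC
bounds on per-cell library size, gene complexity, mitochondrial fraction
and UMI/read ratio; count normalization to 10,000 per cell with highly
expressed genes (>5% of a cell's counts) excluded from the size factor;
natural-log transform; per-cell program scores computed against
expression-matched control genes; and the stem-cell index
``revCSC score − proCSC score`` contrasting the revival versus
proliferative colorectal cancer stem-cell programs.

The canonical container is :class:`anndata.AnnData` (cells × genes); the
numerical core also runs on plain arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"

OBS_TOTAL = "total_umis"
OBS_GENES = "n_genes"
OBS_MITO = "mito_fraction"
OBS_RATIO = "umi_read_ratio"


# ------------------------------------------------------------------ I/O
def read_counts(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path | None = None,
) -> ad.AnnData:
    """Read a MatrixMarket counts triplet (cells × genes) into AnnData."""
    X = sparse.csr_matrix(mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if X.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(barcodes)} barcodes x {len(genes)} genes"
        )
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes), var=pd.DataFrame(index=genes))
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        adata.obs = adata.obs.join(meta)
    return adata


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


def annotate_qc_metadata(adata: ad.AnnData) -> ad.AnnData:
    """Fill in the recomputable per-cell QC metadata from the matrix."""
    X = _dense(adata.X)
    adata.obs[OBS_TOTAL] = X.sum(axis=1).astype(int)
    adata.obs[OBS_GENES] = (X > 0).sum(axis=1).astype(int)
    mito = np.array([g.startswith(MITO_PREFIX) for g in adata.var_names])
    totals = np.maximum(X.sum(axis=1), 1)
    adata.obs[OBS_MITO] = X[:, mito].sum(axis=1) / totals
    return adata


# ------------------------------------------------------------------ QC
@dataclass(frozen=True)
class QCThresholds:
    """Exclusion bounds; a cell is removed if strictly beyond any bound.

    Values exactly at a bound are kept (strict inequalities as printed).
    Note the UMI/read-ratio rule excludes *high*-ratio cells, as listed.
    """

    umi_max: int = 32_500
    umi_min: int = 1_000
    genes_max: int = 7_000
    genes_min: int = 300
    mito_max: float = 0.20
    umi_read_ratio_max: float = 0.4
    min_cells_per_gene: int = 25


@dataclass
class QCReport:
    n_cells_in: int = 0
    n_cells_kept: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    n_genes_in: int = 0
    n_genes_kept: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"rule": "kept", "n_removed": self.n_cells_kept})
        return pd.DataFrame(rows)


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells, then genes detected in too few cells.

    Cell rules are attributed in a fixed precedence order (UMI → genes →
    mito → ratio) for the report; the kept set is order-independent.
    An empty result is valid and returned with a full report.
    """
    t = thresholds or QCThresholds()
    for col in (OBS_TOTAL, OBS_GENES, OBS_MITO):
        if col not in adata.obs.columns:
            adata = annotate_qc_metadata(adata.copy())
            break
    if OBS_RATIO not in adata.obs.columns:
        raise ValueError(f"per-cell metadata column {OBS_RATIO!r} is required for QC")

    umi = adata.obs[OBS_TOTAL].to_numpy(dtype=float)
    genes = adata.obs[OBS_GENES].to_numpy(dtype=float)
    mito = adata.obs[OBS_MITO].to_numpy(dtype=float)
    ratio = adata.obs[OBS_RATIO].to_numpy(dtype=float)

    fail_umi = (umi > t.umi_max) | (umi < t.umi_min)
    fail_genes = (genes > t.genes_max) | (genes < t.genes_min)
    fail_mito = mito > t.mito_max
    fail_ratio = ratio > t.umi_read_ratio_max

    keep = ~(fail_umi | fail_genes | fail_mito | fail_ratio)
    report = QCReport(n_cells_in=adata.n_obs, n_genes_in=adata.n_vars)
    attributed = np.zeros(adata.n_obs, dtype=bool)
    for rule, fail in (
        ("umi", fail_umi),
        ("genes", fail_genes),
        ("mito", fail_mito),
        ("umi_read_ratio", fail_ratio),
    ):
        exclusive = fail & ~attributed
        report.removed[rule] = int(exclusive.sum())
        attributed |= fail

    filtered = adata[keep].copy()
    # gene filter applied after cell filters, on the kept cells
    X = _dense(filtered.X)
    detected_in = (X > 0).sum(axis=0)
    gene_keep = detected_in >= t.min_cells_per_gene
    filtered = filtered[:, gene_keep].copy()
    report.n_cells_kept = filtered.n_obs
    report.n_genes_kept = filtered.n_vars
    return filtered, report


# -------------------------------------------------------------- normalize
def normalize_counts(
    X: np.ndarray, scale: float = 10_000.0, max_fraction: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Count-based normalization excluding highly expressed genes.

    Per cell, genes individually comprising more than ``max_fraction`` of
    that cell's total are excluded from the size-factor base:
    ``size_factor = base_total / scale``; every gene's count (including the
    excluded ones) is divided by the cell's size factor.

    Returns ``(normalized, kept_mask)``; cells whose base total is 0 are
    flagged False in ``kept_mask`` (their rows are NaN) and should be
    dropped with a warning by the caller.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a cells x genes matrix")
    totals = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, X / np.maximum(totals, 1), 0.0)
    high = frac > max_fraction
    base = np.where(~high, X, 0.0).sum(axis=1)
    kept = base > 0
    factors = np.where(kept, base, np.nan) / scale
    normalized = X / factors[:, None]
    if not kept.all():
        warnings.warn(
            f"{int((~kept).sum())} cell(s) with no counts outside highly expressed "
            "genes were flagged for dropping"
        )
    return normalized, kept


def log_transform(X: np.ndarray) -> np.ndarray:
    """Natural-log transform ln(1 + x), recorded as its own step."""
    return np.log1p(np.asarray(X, dtype=float))


def log_normalize(
    adata: ad.AnnData, scale: float = 10_000.0, max_fraction: float = 0.05
) -> ad.AnnData:
    """Normalize then natural-log transform an AnnData; drops flagged cells."""
    normalized, kept = normalize_counts(_dense(adata.X), scale, max_fraction)
    out = adata[kept].copy()
    out.layers["counts"] = _dense(out.X)
    out.X = log_transform(normalized[kept])
    out.uns["normalization"] = {"scale": scale, "max_fraction": max_fraction, "log": "ln(1+x)"}
    return out


# ------------------------------------------------------------ program score
class GeneProgramScorer:
    """Per-cell program score against expression-matched control genes.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins; for every program gene,
    ``n_control_per_gene`` control genes are sampled (seeded) from its bin,
    excluding all program genes; the score is the per-cell mean program
    expression minus the mean expression of the pooled control set.

    sklearn-style: ``fit(X)`` with a cells × genes DataFrame learns the
    binning and control set (``control_genes_``); ``transform(X)`` returns
    the per-cell scores.
    """

    def __init__(
        self,
        program_genes: list[str],
        n_bins: int = 25,
        n_control_per_gene: int = 50,
        random_state: int = 0,
    ):
        self.program_genes = list(program_genes)
        self.n_bins = n_bins
        self.n_control_per_gene = n_control_per_gene
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "program_genes": self.program_genes,
            "n_bins": self.n_bins,
            "n_control_per_gene": self.n_control_per_gene,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "GeneProgramScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "GeneProgramScorer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("GeneProgramScorer expects a cells x genes DataFrame")
        present = [g for g in self.program_genes if g in X.columns]
        dropped = sorted(set(self.program_genes) - set(present))
        if dropped:
            logger.warning("program genes missing from matrix, dropped: %s", dropped)
        if not present:
            raise ValueError("program is empty after dropping missing genes")
        self.used_program_genes_ = present

        means = X.mean(axis=0)
        # equal-frequency bins over the mean-expression ranks
        n_items = max(int(np.round(len(means) / max(self.n_bins - 1, 1))), 1)
        bins = (means.rank(method="min") // n_items).astype(int)

        rng = np.random.default_rng(self.random_state)
        program_set = set(present)
        controls: set[str] = set()
        for gene in present:
            pool = bins.index[(bins == bins[gene]) & ~bins.index.isin(program_set)]
            if len(pool) == 0:
                continue
            take = min(self.n_control_per_gene, len(pool))
            controls.update(rng.choice(np.asarray(pool, dtype=object), take, replace=False))
        if not controls:
            raise ValueError("no control genes available outside the program")
        self.control_genes_ = sorted(controls)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "control_genes_"):
            raise RuntimeError("GeneProgramScorer is not fitted")
        prog = X[self.used_program_genes_].to_numpy(dtype=float).mean(axis=1)
        ctrl = X[self.control_genes_].to_numpy(dtype=float).mean(axis=1)
        return prog - ctrl

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def score_gene_program(
    lognorm: pd.DataFrame | ad.AnnData,
    program_genes: list[str],
    n_control_per_gene: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Functional wrapper over :class:`GeneProgramScorer`."""
    if isinstance(lognorm, ad.AnnData):
        lognorm = pd.DataFrame(
            _dense(lognorm.X), index=lognorm.obs_names, columns=lognorm.var_names
        )
    scorer = GeneProgramScorer(
        program_genes,
        n_bins=n_bins,
        n_control_per_gene=n_control_per_gene,
        random_state=seed,
    )
    return scorer.fit_transform(lognorm)


# --------------------------------------------------------------- stem index
@dataclass
class StemScores:
    """Per-cell program scores and the derived stem-cell index."""

    cell_ids: list[str]
    pro_score: np.ndarray
    rev_score: np.ndarray

    @property
    def stem_index(self) -> np.ndarray:
        return self.rev_score - self.pro_score

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cell_ids,
                "proCSC_score": self.pro_score,
                "revCSC_score": self.rev_score,
                "stem_index": self.stem_index,
            }
        )


def stem_cell_index(pro_scores, rev_scores) -> np.ndarray:
    """Stem-cell index = revCSC score − proCSC score, per cell."""
    pro = np.asarray(pro_scores, dtype=float)
    rev = np.asarray(rev_scores, dtype=float)
    if pro.shape != rev.shape:
        raise ValueError("proCSC and revCSC score vectors are misaligned")
    return rev - pro


def stem_index_summary(index: np.ndarray, sample_labels=None) -> pd.DataFrame:
    """Median and quartiles of the stem index, overall or per sample."""
    index = np.asarray(index, dtype=float)
    labels = np.asarray(sample_labels) if sample_labels is not None else np.full(index.size, "all")
    rows = []
    for s in pd.unique(labels):
        v = index[labels == s]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"sample": s, "q1": q1, "median": med, "q3": q3, "n_cells": v.size})
    return pd.DataFrame(rows)


def compute_stem_scores(
    adata: ad.AnnData,
    pro_genes: list[str],
    rev_genes: list[str],
    n_control_per_gene: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> StemScores:
    """QC'd + log-normalized AnnData -> per-cell proCSC/revCSC/stem index."""
    if set(pro_genes) & set(rev_genes):
        raise ValueError("proCSC and revCSC gene sets must be disjoint")
    df = pd.DataFrame(_dense(adata.X), index=adata.obs_names, columns=adata.var_names)
    pro = score_gene_program(df, pro_genes, n_control_per_gene, n_bins, seed)
    rev = score_gene_program(df, rev_genes, n_control_per_gene, n_bins, seed)
    return StemScores(cell_ids=list(adata.obs_names), pro_score=pro, rev_score=rev)
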