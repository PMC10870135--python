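"""Input/output and cell-level quality control.

Reads cell x gene expression matrices (Matrix Market triplets with gene/barcode
label files, dense TSV, or an AnnData ``.h5ad`` container) together with a
per-cell metadata table, applies the configurable QC and cluster-fraction
filters, and produces the normalized :class:`AnnotatedMatrix` that the feature
extraction stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import DimensionError, EmptyResultError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_META_COLUMNS = ("cell_id", "cluster", "stage")
OPTIONAL_META_COLUMNS = ("pseudotime", "doublet_score", "pct_mito", "pct_ribo")


def _stage_sort_key(label: str):
    """Order stage labels numerically where possible (E9.5 < E10.5, day counts)."""
    s = str(label).lstrip("ESPsp")
    try:
        return (0, float(s))
    except ValueError:
        return (1, str(label))


@dataclass
class AnnotatedMatrix:
    """Cells x genes expression with per-cell cluster/stage/pseudotime metadata.

    ``counts`` holds raw UMI counts; ``norm`` is unset until :func:`normalize`
    is called. ``cell_meta`` rows align with matrix rows.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: np.ndarray
    norm: sp.csr_matrix | None = None
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.cell_meta):
            raise DimensionError(
                f"matrix has {self.counts.shape[0]} cells but cell metadata has "
                f"{len(self.cell_meta)} rows"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise DimensionError(
                f"matrix has {self.counts.shape[1]} genes but {len(self.gene_ids)} "
                "gene identifiers were supplied"
            )
        if self.norm is not None and self.norm.shape != self.counts.shape:
            raise DimensionError(
                f"norm shape {self.norm.shape} != counts shape {self.counts.shape}"
            )
        genes = pd.Index(self.gene_ids)
        if genes.has_duplicates or (genes == "").any():
            raise SchemaError("gene identifiers must be unique and non-empty")
        for col in REQUIRED_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise SchemaError(f"cell metadata lacks required column '{col}'")
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        if not self.stage_order:
            self.stage_order = sorted(
                self.cell_meta["stage"].astype(str).unique(), key=_stage_sort_key
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            counts=self.counts[mask],
            norm=None if self.norm is None else self.norm[mask],
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            stage_order=list(self.stage_order),
        )


@dataclass
class QCConfig:
    """Cell-level QC thresholds; comparisons are strict inequalities."""

    min_umi: int = 1000
    min_genes: int = 500
    max_pct_mito: float = 10.0
    max_pct_ribo: float = 50.0
    max_doublet_score: float = 0.2
    min_cluster_fraction: float = 0.04
    excluded_clusters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("min_umi", "min_genes", "max_pct_mito", "max_pct_ribo",
                     "max_doublet_score", "min_cluster_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"QC threshold {name} must be non-negative")
        if not 0 <= self.min_cluster_fraction < 1:
            raise ValueError("min_cluster_fraction must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _read_labels(path: Path) -> list[str]:
    """First column of a headerless TSV (CellRanger genes/barcodes convention)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_expression(
    matrix_path: str | Path,
    cell_meta_path: str | Path,
    format: str = "mtx",
    gene_path: str | Path | None = None,
    barcode_path: str | Path | None = None,
) -> AnnotatedMatrix:
    """Load raw counts plus cell metadata into an :class:`AnnotatedMatrix`.

    ``mtx`` follows the CellRanger convention (genes as rows) and is transposed
    on load; ``dense_tsv`` has cells as rows and genes as columns;
    ``h5_container`` is an AnnData ``.h5ad`` file whose ``X`` holds counts.
    """
    matrix_path = Path(matrix_path)
    meta = pd.read_csv(cell_meta_path, sep="\t", dtype={"cell_id": str, "cluster": str,
                                                        "stage": str})
    for col in REQUIRED_META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"cell metadata lacks required column '{col}'")

    if format == "mtx":
        counts = sp.csr_matrix(scipy.io.mmread(matrix_path).T)
        gene_path = Path(gene_path) if gene_path else matrix_path.parent / "genes.tsv"
        barcode_path = (
            Path(barcode_path) if barcode_path else matrix_path.parent / "barcodes.tsv"
        )
        gene_ids = np.asarray(_read_labels(gene_path), dtype=object)
        barcodes = _read_labels(barcode_path)
        if len(barcodes) != counts.shape[0]:
            raise DimensionError(
                f"matrix has {counts.shape[0]} cells but barcode file has "
                f"{len(barcodes)} entries"
            )
    elif format == "dense_tsv":
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = sp.csr_matrix(frame.to_numpy())
        gene_ids = np.asarray(frame.columns, dtype=object)
    elif format == "h5_container":
        import anndata

        adata = anndata.read_h5ad(matrix_path)
        counts = sp.csr_matrix(adata.X)
        gene_ids = np.asarray(adata.var_names, dtype=object)
    else:
        raise ValueError(f"unknown expression format '{format}'")

    if len(meta) != counts.shape[0]:
        raise DimensionError(
            f"matrix has {counts.shape[0]} cells but cell metadata has "
            f"{len(meta)} rows"
        )
    return AnnotatedMatrix(counts=counts, cell_meta=meta, gene_ids=gene_ids)


def qc_filter(am: AnnotatedMatrix, cfg: QCConfig) -> AnnotatedMatrix:
    """Retain cells passing all configured QC thresholds (strict comparisons).

    Criteria whose metadata column is absent are skipped with a warning.
    """
    umi = np.asarray(am.counts.sum(axis=1)).ravel()
    n_genes = np.asarray((am.counts > 0).sum(axis=1)).ravel()
    keep = (umi > cfg.min_umi) & (n_genes > cfg.min_genes)

    for col, bound, sense in (
        ("pct_mito", cfg.max_pct_mito, "<"),
        ("pct_ribo", cfg.max_pct_ribo, "<"),
        ("doublet_score", cfg.max_doublet_score, "<"),
    ):
        if col in am.cell_meta.columns:
            vals = am.cell_meta[col].to_numpy(dtype=float)
            # a missing value in a present column does not fail the cell
            keep &= (vals < bound) | np.isnan(vals)
        else:
            logger.warning("QC column '%s' absent; criterion %s %s skipped",
                           col, sense, bound)

    if not keep.any():
        raise EmptyResultError("QC filter removed every cell")
    return am.subset_cells(keep)


def cluster_fraction_filter(am: AnnotatedMatrix, cfg: QCConfig) -> AnnotatedMatrix:
    """Drop cells of rare clusters (< min_cluster_fraction of post-QC cells)
    and of explicitly excluded clusters. Fractions are computed once on the
    input, not iteratively."""
    clusters = am.cell_meta["cluster"].astype(str)
    frac = clusters.value_counts(normalize=True)
    bad = set(frac.index[frac < cfg.min_cluster_fraction]) | set(cfg.excluded_clusters)
    if bad:
        logger.info("removing clusters: %s", sorted(bad))
    keep = ~clusters.isin(bad).to_numpy()
    if not keep.any():
        raise EmptyResultError("cluster-fraction filter removed every cell")
    return am.subset_cells(keep)


def normalize(am: AnnotatedMatrix, scale_target: float = 1e4) -> AnnotatedMatrix:
    """Library-size normalization followed by natural log1p.

    norm[i, j] = log(1 + counts[i, j] * scale_target / library_size_i).
    """
    lib = np.asarray(am.counts.sum(axis=1)).ravel()
    if np.any(lib == 0):
        raise ArithmeticError("cells with zero library size must be removed by QC")
    scaled = sp.diags(scale_target / lib) @ am.counts.tocsr()
    scaled.data = np.log1p(scaled.data)
    return replace(am, norm=sp.csr_matrix(scaled))


def write_ranked_genes(result, path: str | Path) -> None:
    """Write the ranked gene table (score descending, ties lexicographic)."""
    scores = result.scores
    frame = pd.DataFrame({
        "gene_id": scores.index.astype(str),
        "stigma_score": scores.to_numpy(dtype=float),
    })
    frame = frame.sort_values(
        ["stigma_score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    training = set(result.training_genes)
    frame["above_threshold"] = frame["stigma_score"] > result.threshold
    frame["in_training_class"] = frame["gene_id"].isin(training)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ranked_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
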