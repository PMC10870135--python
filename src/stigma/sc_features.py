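"""Per-cluster gene expression features and the gene-retention filter.

Each gene is summarized per cell cluster by four statistics over normalized
expression: mean, unbiased variance, fraction of cells expressing (raw count
> 0), and log2 fold change of the cluster mean against the mean of all other
cells (+1 pseudocount on both sides). A pseudo-bulk mode collapses all cells
into one cluster for the ablation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, EmptyResultError
from .io_qc import AnnotatedMatrix


@dataclass
class ClusterFeatureTable:
    """Four (genes x clusters) matrices sharing axis labels."""

    genes: np.ndarray
    clusters: list[str]
    mean: np.ndarray
    variance: np.ndarray
    frac_expressing: np.ndarray
    log_fc: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        shape = (len(self.genes), len(self.clusters))
        for name in ("mean", "variance", "frac_expressing", "log_fc"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != shape:
                raise ValueError(f"{name} has shape {mat.shape}, expected {shape}")
            setattr(self, name, mat)
        if (self.variance < 0).any():
            raise ValueError("variance must be non-negative")
        if ((self.frac_expressing < 0) | (self.frac_expressing > 1)).any():
            raise ValueError("frac_expressing must lie in [0, 1]")

    def subset_genes(self, mask: np.ndarray) -> "ClusterFeatureTable":
        return ClusterFeatureTable(
            genes=self.genes[mask],
            clusters=list(self.clusters),
            mean=self.mean[mask],
            variance=self.variance[mask],
            frac_expressing=self.frac_expressing[mask],
            log_fc=self.log_fc[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, cluster, mean, variance, frac_expressing, log_fc."""
        rows = []
        for j, cl in enumerate(self.clusters):
            rows.append(pd.DataFrame({
                "gene": self.genes,
                "cluster": cl,
                "mean": self.mean[:, j],
                "variance": self.variance[:, j],
                "frac_expressing": self.frac_expressing[:, j],
                "log_fc": self.log_fc[:, j],
            }))
        return pd.concat(rows, ignore_index=True)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _cluster_indicator(labels: pd.Series, clusters: list[str]) -> sp.csr_matrix:
    """Sparse clusters x cells membership indicator."""
    idx = pd.Categorical(labels.astype(str), categories=clusters).codes
    n = len(labels)
    return sp.csr_matrix(
        (np.ones(n), (idx, np.arange(n))), shape=(len(clusters), n)
    )


def _features_for_grouping(am: AnnotatedMatrix, labels: pd.Series,
                           clusters: list[str], with_fc: bool) -> ClusterFeatureTable:
    if am.norm is None:
        raise ConfigurationError("normalize() must be called before feature extraction")
    ind = _cluster_indicator(labels, clusters)
    sizes = np.asarray(ind.sum(axis=1)).ravel()  # cells per cluster
    norm = am.norm.tocsr()

    sums = (ind @ norm).toarray()                       # clusters x genes
    sumsq = (ind @ norm.multiply(norm)).toarray()
    mean = sums / sizes[:, None]
    # unbiased sample variance; clusters of one cell get 0 by convention
    denom = np.maximum(sizes - 1, 1)[:, None]
    var = np.maximum(sumsq - sizes[:, None] * mean**2, 0.0) / denom
    var[sizes == 1] = 0.0

    frac = (ind @ (am.counts > 0)).toarray() / sizes[:, None]

    if with_fc:
        total = sums.sum(axis=0)
        n_total = sizes.sum()
        mean_out = (total[None, :] - sums) / (n_total - sizes)[:, None]
        log_fc = np.log2((mean + 1.0) / (mean_out + 1.0))
    else:
        log_fc = np.zeros_like(mean)

    return ClusterFeatureTable(
        genes=am.gene_ids,
        clusters=clusters,
        mean=mean.T,
        variance=var.T,
        frac_expressing=frac.T,
        log_fc=log_fc.T,
    )


def per_cluster_features(am: AnnotatedMatrix) -> ClusterFeatureTable:
    """Mean / variance / fraction-expressing / log2 fold change per (gene, cluster).

    Cluster order is the sorted set of labels, so the output is invariant to
    cell order.
    """
    labels = am.cell_meta["cluster"].astype(str)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ConfigurationError(
            "fold change needs at least 2 clusters; got " + repr(clusters)
        )
    return _features_for_grouping(am, labels, clusters, with_fc=True)


def pseudobulk_features(am: AnnotatedMatrix) -> ClusterFeatureTable:
    """Single-column table over all cells (log_fc fixed at 0 by convention)."""
    labels = pd.Series(["pseudobulk"] * am.n_cells)
    return _features_for_grouping(am, labels, ["pseudobulk"], with_fc=False)


def retain_expressed_genes(cft: ClusterFeatureTable) -> ClusterFeatureTable:
    """Keep genes with mean expression > 0 in at least one cluster."""
    mask = cft.mean.max(axis=1) > 0
    if not mask.any():
        raise EmptyResultError("no gene has positive mean expression in any cluster")
    return cft.subset_genes(mask)
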