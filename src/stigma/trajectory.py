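"""Pseudotime binning and cubic B-spline coefficient extraction.

Per cluster, cells are ordered on a [0, 1] pseudotime (either rescaled from a
precomputed column or derived from ordered developmental stages), gene
expression is averaged inside 20 equal-width pseudotime bins, and each gene's
binned profile is summarized by the coefficients of a least-squares fit to a
clamped cubic B-spline basis with 10 coefficients ("control points"). The
coefficient vectors are the temporal features of the classifier.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .errors import ConfigurationError, SchemaError
from .io_qc import AnnotatedMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplineBasis:
    """Clamped (open-uniform) B-spline basis on [0, 1]."""

    degree: int
    n_basis: int
    knots: np.ndarray

    def design_matrix(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``t`` (rows sum to 1 on [0, 1])."""
        t = np.asarray(t, dtype=float)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()


def build_basis(degree: int = 3, n_basis: int = 10) -> SplineBasis:
    """Clamped knot vector: degree+1 repeats at 0 and 1, the remaining
    n_basis - degree - 1 interior knots equally spaced on (0, 1)."""
    if n_basis < degree + 1:
        raise ConfigurationError(
            f"n_basis ({n_basis}) must be at least degree+1 ({degree + 1})"
        )
    n_interior = n_basis - degree - 1
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    return SplineBasis(degree=degree, n_basis=n_basis, knots=knots)


@dataclass
class BinnedProfile:
    """Non-empty pseudotime bins of one gene in one cluster."""

    gene: str
    cluster: str
    bin_centers: np.ndarray
    bin_means: np.ndarray
    n_cells_per_bin: np.ndarray


@dataclass
class BinnedExpression:
    """Binned profiles of all genes of one cluster (bins shared across genes)."""

    cluster: str
    genes: np.ndarray
    bin_centers: np.ndarray           # non-empty bins only, increasing
    bin_means: np.ndarray             # bins x genes
    n_cells_per_bin: np.ndarray

    def profile(self, gene: str) -> BinnedProfile:
        j = int(np.flatnonzero(self.genes == gene)[0])
        return BinnedProfile(
            gene=gene,
            cluster=self.cluster,
            bin_centers=self.bin_centers,
            bin_means=self.bin_means[:, j],
            n_cells_per_bin=self.n_cells_per_bin,
        )


@dataclass
class TrajectoryFeatureTable:
    """genes x clusters x n_basis spline coefficient tensor."""

    genes: np.ndarray
    clusters: list[str]
    coefficients: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n_basis = self.coefficients.shape[2]
        rows = []
        for j, cl in enumerate(self.clusters):
            block = pd.DataFrame(
                self.coefficients[:, j, :],
                columns=[f"coef_{k}" for k in range(n_basis)],
            )
            block.insert(0, "cluster", cl)
            block.insert(0, "gene", self.genes)
            rows.append(block)
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def assign_pseudotime(
    am: AnnotatedMatrix, cluster: str, mode: str = "precomputed", seed: int = 0
) -> pd.Series:
    """Pseudotime in [0, 1] for the cells of one cluster.

    ``precomputed``: the pseudotime column min-max rescaled within the cluster.
    ``stage_rank``: each cell mapped to (stage_index + u) / n_stages with a
    deterministic, seeded within-stage offset u in [0, 1), so the earliest
    stage occupies the lowest pseudotime and all values are unique.
    """
    in_cluster = am.cell_meta["cluster"].astype(str) == str(cluster)
    idx = np.flatnonzero(in_cluster.to_numpy())
    if len(idx) == 0:
        raise ConfigurationError(f"cluster '{cluster}' has no cells")

    if mode == "precomputed":
        if "pseudotime" not in am.cell_meta.columns:
            raise SchemaError("pseudotime column required for mode='precomputed'")
        vals = am.cell_meta["pseudotime"].to_numpy(dtype=float)[idx]
        if np.isnan(vals).any():
            raise SchemaError("pseudotime column contains missing values "
                              f"in cluster '{cluster}'")
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            vals = (vals - lo) / (hi - lo)
        else:
            logger.warning("constant pseudotime in cluster '%s'; using 0.5", cluster)
            vals = np.full(len(idx), 0.5)
        return pd.Series(vals, index=idx)

    if mode == "stage_rank":
        stages = am.cell_meta["stage"].astype(str).to_numpy()[idx]
        present = [s for s in am.stage_order if s in set(stages)]
        n_stages = len(present)
        out = np.empty(len(idx), dtype=float)
        cl_salt = zlib.crc32(str(cluster).encode())
        if n_stages == 1:
            logger.warning(
                "single stage in cluster '%s'; spreading cells uniformly on [0,1]",
                cluster,
            )
        for si, stage in enumerate(present):
            pos = np.flatnonzero(stages == stage)
            rng = np.random.default_rng([seed, cl_salt, si])
            perm = rng.permutation(len(pos))
            u = perm / len(pos)                      # unique offsets in [0, 1)
            if n_stages == 1:
                out[pos] = (perm + 0.5) / len(pos)
            else:
                out[pos] = (si + u) / n_stages
        return pd.Series(out, index=idx)

    raise ValueError(f"unknown pseudotime mode '{mode}'")


def bin_expression(
    am: AnnotatedMatrix,
    pseudotime: pd.Series,
    n_bins: int = 20,
    cluster: str = "",
) -> BinnedExpression:
    """Average normalized expression inside equal-width pseudotime bins.

    Bins are half-open [k/n, (k+1)/n) with the last bin closed; empty bins are
    omitted. Bin centers are (k + 0.5) / n.
    """
    if am.norm is None:
        raise ConfigurationError("normalize() must be called before binning")
    if n_bins < 2:
        raise ConfigurationError("n_bins must be at least 2")
    t = pseudotime.to_numpy(dtype=float)
    cells = pseudotime.index.to_numpy()
    which = np.minimum((t * n_bins).astype(int), n_bins - 1)  # t==1 -> last bin

    norm = am.norm[cells]
    counts = np.bincount(which, minlength=n_bins)
    nonempty = np.flatnonzero(counts)
    ind = sp.csr_matrix(
        (np.ones(len(which)), (which, np.arange(len(which)))),
        shape=(n_bins, len(which)),
    )
    sums = (ind @ norm).toarray()
    means = sums[nonempty] / counts[nonempty, None]
    centers = (nonempty + 0.5) / n_bins
    return BinnedExpression(
        cluster=str(cluster),
        genes=am.gene_ids,
        bin_centers=centers,
        bin_means=means,
        n_cells_per_bin=counts[nonempty],
    )


def _solve_ridge_lstsq(B: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """min ||B b - y||^2 + ridge ||b||^2 via the augmented least-squares system."""
    n_basis = B.shape[1]
    aug_B = np.vstack([B, np.sqrt(ridge) * np.eye(n_basis)])
    aug_Y = np.vstack([Y, np.zeros((n_basis, Y.shape[1]))])
    beta, *_ = np.linalg.lstsq(aug_B, aug_Y, rcond=None)
    return beta


def fit_spline_coefficients(
    profile: BinnedProfile, basis: SplineBasis, ridge: float = 1e-8
) -> np.ndarray:
    """Ridge-stabilized unweighted least-squares spline coefficients."""
    if len(profile.bin_centers) < 1:
        raise ConfigurationError("profile has no non-empty bins")
    B = basis.design_matrix(profile.bin_centers)
    y = np.asarray(profile.bin_means, dtype=float)[:, None]
    return _solve_ridge_lstsq(B, y, ridge)[:, 0]


def trajectory_features(
    am: AnnotatedMatrix,
    mode: str = "precomputed",
    n_bins: int = 20,
    basis: SplineBasis | None = None,
    ridge: float = 1e-8,
    seed: int = 0,
) -> TrajectoryFeatureTable:
    """Pseudotime ordering, binning, and spline fitting, per cluster.

    Genes with zero expression in a cluster receive the all-zero coefficient
    vector (a zero profile is a legitimate constant fit).
    """
    basis = basis or build_basis()
    clusters = sorted(am.cell_meta["cluster"].astype(str).unique())
    coefs = np.full((am.n_genes, len(clusters), basis.n_basis), np.nan)
    for j, cl in enumerate(clusters):
        pt = assign_pseudotime(am, cl, mode=mode, seed=seed)
        binned = bin_expression(am, pt, n_bins=n_bins, cluster=cl)
        B = basis.design_matrix(binned.bin_centers)
        coefs[:, j, :] = _solve_ridge_lstsq(B, binned.bin_means, ridge).T
        # genes silent in this cluster: exact zero vector
        cells = pt.index.to_numpy()
        expressed = np.asarray(am.norm[cells].sum(axis=0)).ravel() > 0
        coefs[~expressed, j, :] = 0.0
    return TrajectoryFeatureTable(genes=am.gene_ids, clusters=clusters,
                                  coefficients=coefs)
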