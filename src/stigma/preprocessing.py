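"""Feature-matrix conditioning: chained-equation imputation, min-max scaling,
and adaptive synthetic (ADASYN) minority oversampling.

ADASYN allocates synthetic points to minority samples in proportion to the
fraction of majority neighbors around them, then interpolates each synthetic
point on the segment between a minority sample and one of its k nearest
minority neighbors; a seeded trim/top-up enforces exact class balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def iterative_impute(
    frame: pd.DataFrame, max_iter: int = 10, tol: float = 1e-3
) -> pd.DataFrame:
    """Chained-equations imputation with per-column linear least squares.

    Missing cells start at their column mean; columns with missingness are
    revisited in fixed column order, each regressed on all other columns over
    its observed rows, and the predictions overwrite only the missing cells.
    Iteration stops when the largest change of any imputed cell drops below
    ``tol``. Observed cells are never modified. Entirely missing columns are
    dropped with a warning.
    """
    frame = frame.copy()
    all_missing = [c for c in frame.columns if frame[c].isna().all()]
    if all_missing:
        logger.warning("dropping entirely missing columns: %s", all_missing)
        frame = frame.drop(columns=all_missing)

    X = frame.to_numpy(dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        return frame
    col_means = np.nanmean(X, axis=0)
    filled = np.where(missing, col_means[None, :], X)

    target_cols = [j for j in range(X.shape[1]) if missing[:, j].any()]
    for _ in range(max_iter):
        max_delta = 0.0
        for j in target_cols:
            obs = ~missing[:, j]
            others = np.delete(filled, j, axis=1)
            design = np.column_stack([np.ones(len(filled)), others])
            beta, *_ = np.linalg.lstsq(design[obs], X[obs, j], rcond=None)
            pred = design[~obs] @ beta
            max_delta = max(max_delta, np.max(np.abs(filled[~obs, j] - pred),
                                              initial=0.0))
            filled[~obs, j] = pred
        if max_delta < tol:
            break
    return pd.DataFrame(filled, index=frame.index, columns=frame.columns)


@dataclass
class ScalingParams:
    """Training-derived per-column min/max for [0, 1] scaling with clipping."""

    col_min: pd.Series
    col_max: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        span = (self.col_max - self.col_min).replace(0.0, 1.0)
        out = (frame[self.col_min.index] - self.col_min) / span
        return out.clip(0.0, 1.0)


def minmax_scale(frame: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Map each column to [0, 1]; constant columns map to 0 with a warning."""
    col_min = frame.min(axis=0)
    col_max = frame.max(axis=0)
    constant = col_min.index[(col_max - col_min) == 0]
    if len(constant):
        logger.warning("constant feature columns scaled to 0: %s",
                       list(constant[:5]))
    params = ScalingParams(col_min=col_min, col_max=col_max)
    return params.transform(frame), params


def adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a two-class dataset by adaptive synthetic minority oversampling.

    Returns (X', y') where the minority class has been topped up to exactly
    the majority count. Synthetic points are convex combinations of two real
    minority points. Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ConfigurationError(f"ADASYN needs exactly 2 classes, got {labels}")
    minority = labels[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    G = int(n_maj - n_min)
    if G == 0:
        return X, y

    X_min = X[y == minority]
    if n_min < 2:
        raise ConfigurationError("minority class too small to interpolate")
    if n_min < k + 1:
        k_eff = int(n_min - 1)
        logger.warning("minority class smaller than k+1; reducing k to %d", k_eff)
    else:
        k_eff = k

    rng = np.random.default_rng(seed)

    # ratio of majority members among the k nearest neighbors in the full data
    nn_all = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    _, idx = nn_all.kneighbors(X_min)
    neighbor_labels = y[idx[:, 1:]]             # drop self
    r = (neighbor_labels != minority).mean(axis=1)
    r_hat = r / r.sum() if r.sum() > 0 else np.full(len(r), 1.0 / len(r))
    g = np.round(r_hat * G).astype(int)

    # k nearest neighbors within the minority class, for interpolation
    nn_min = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
    _, min_idx = nn_min.kneighbors(X_min)
    min_idx = min_idx[:, 1:]

    seeds, partners = [], []
    for i in range(len(X_min)):
        for _ in range(g[i]):
            seeds.append(i)
            partners.append(rng.choice(min_idx[i]))
    seeds = np.array(seeds, dtype=int)
    partners = np.array(partners, dtype=int)

    # enforce exact balance: trim surplus or top up shortfall, seeded
    if len(seeds) > G:
        keep = rng.choice(len(seeds), size=G, replace=False)
        keep.sort()
        seeds, partners = seeds[keep], partners[keep]
    while len(seeds) < G:
        i = int(rng.integers(len(X_min)))
        seeds = np.append(seeds, i)
        partners = np.append(partners, rng.choice(min_idx[i]))

    lam = rng.uniform(size=(G, 1))
    synth = X_min[seeds] + lam * (X_min[partners] - X_min[seeds])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(G, minority, dtype=y.dtype)])
    return X_out, y_out
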