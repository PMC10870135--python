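"""The gene-prioritization classifier.

:class:`StigmaModel` assembles per-gene features (cluster-level expression
statistics, pseudotime spline coefficients, gene-intrinsic properties), and
``fit`` runs the classification pipeline — chained imputation, min-max
scaling, ADASYN oversampling inside training folds, a recall-optimized grid
search over random-forest hyperparameters, 5-fold cross-validated metrics, a
density-zero score threshold from the negative class, and genome-wide scoring
— returning a :class:`StigmaResults` with estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, auc, precision_score, recall_score,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, SchemaError
from .gene_properties import PROPERTY_COLUMNS
from .preprocessing import adasyn_oversample, iterative_impute, minmax_scale
from .sc_features import (ClusterFeatureTable, per_cluster_features,
                          pseudobulk_features, retain_expressed_genes)
from .trajectory import TrajectoryFeatureTable, build_basis, trajectory_features
from .training_classes import TrainingClasses

logger = logging.getLogger(__name__)

FEATURE_BLOCK_MODES = ("full", "pseudobulk_only", "cluster_only", "no_trajectory")


def _child_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2**31."""
    h = hashlib.blake2b(np.array([seed, *tags], dtype=np.int64).tobytes(),
                        digest_size=4).digest()
    return int.from_bytes(h, "little") % (2**31 - 1)


@dataclass
class FeatureMatrix:
    """Genes x named features with missing markers and optional class labels."""

    data: pd.DataFrame
    labels: pd.Series  # 'positive' | 'negative' | 'unlabeled' per gene

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise SchemaError("feature names must be unique")
        self.labels = self.labels.reindex(self.data.index).fillna("unlabeled")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def assemble_features(
    cft: ClusterFeatureTable,
    tft: TrajectoryFeatureTable | None = None,
    props: pd.DataFrame | None = None,
    classes: TrainingClasses | None = None,
) -> FeatureMatrix:
    """One row per retained gene; deterministic column order: expression block
    by cluster, trajectory block by cluster, property block in fixed order."""
    genes = pd.Index(cft.genes, name="gene")
    blocks: list[pd.DataFrame] = []

    sc_cols = {}
    for j, cl in enumerate(cft.clusters):
        sc_cols[f"sc.mean.{cl}"] = cft.mean[:, j]
        sc_cols[f"sc.var.{cl}"] = cft.variance[:, j]
        sc_cols[f"sc.frac.{cl}"] = cft.frac_expressing[:, j]
        sc_cols[f"sc.fc.{cl}"] = cft.log_fc[:, j]
    blocks.append(pd.DataFrame(sc_cols, index=genes))

    if tft is not None:
        tgenes = pd.Index(tft.genes)
        traj_cols = {}
        for j, cl in enumerate(tft.clusters):
            for k in range(tft.coefficients.shape[2]):
                traj_cols[f"traj.{cl}.coef_{k}"] = pd.Series(
                    tft.coefficients[:, j, k], index=tgenes
                ).reindex(genes).to_numpy()
        blocks.append(pd.DataFrame(traj_cols, index=genes))

    if props is not None:
        cols = [c for c in PROPERTY_COLUMNS if c in props.columns]
        prop_block = props[cols].reindex(genes)
        prop_block.columns = [f"prop.{c}" for c in cols]
        blocks.append(prop_block)

    data = pd.concat(blocks, axis=1)
    labels = pd.Series("unlabeled", index=genes, dtype=object)
    if classes is not None:
        labels[labels.index.isin(classes.positive)] = "positive"
        labels[labels.index.isin(classes.negative)] = "negative"
        if not (labels != "unlabeled").any():
            raise ConfigurationError("no labeled gene appears in the feature matrix")
    return FeatureMatrix(data=data, labels=labels)


@dataclass
class HyperparameterGrid:
    """Search space; defaults bracket the selected values of both published
    disease models (limb / heart)."""

    adasyn_n_neighbors: list[int] = field(default_factory=lambda: [5, 10])
    n_estimators: list[int] = field(default_factory=lambda: [90, 130])
    max_depth: list[int] = field(default_factory=lambda: [15, 30])
    min_samples_split: list[int] = field(default_factory=lambda: [2, 5])
    min_samples_leaf: list[int] = field(default_factory=lambda: [1])

    def __post_init__(self) -> None:
        for name in ("adasyn_n_neighbors", "n_estimators", "max_depth",
                     "min_samples_split", "min_samples_leaf"):
            vals = getattr(self, name)
            if not vals or any(int(v) <= 0 for v in vals):
                raise ConfigurationError(f"grid entry {name} must be positive ints")

    def iter_params(self):
        names = ["adasyn_n_neighbors", "n_estimators", "max_depth",
                 "min_samples_split", "min_samples_leaf"]
        for combo in itertools.product(*(getattr(self, n) for n in names)):
            yield dict(zip(names, combo))


def _make_forest(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_split=params["min_samples_split"],
        min_samples_leaf=params["min_samples_leaf"],
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _fold_fit_predict(X, y, tr, va, params, seed, fold):
    """Oversample the training fold only, fit, return positive-class proba."""
    Xs, ys = adasyn_oversample(
        X[tr], y[tr], k=params["adasyn_n_neighbors"],
        seed=_child_seed(seed, 101, fold),
    )
    clf = _make_forest(params, _child_seed(seed, 202, fold))
    clf.fit(Xs, ys)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(X[va])[:, pos_col]


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Exhaustive grid evaluation by mean positive-class recall over
    stratified folds; oversampling is fit inside each training fold only.
    Ties break by grid iteration order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for _, va in splits:
        if len(np.unique(y[va])) < 2:
            raise ConfigurationError("a validation fold holds a single class")
    best_params, best_recall = None, -np.inf
    for params in grid.iter_params():
        recalls = []
        for fold, (tr, va) in enumerate(splits):
            proba = _fold_fit_predict(X, y, tr, va, params, seed, fold)
            recalls.append(recall_score(y[va], (proba >= 0.5).astype(int)))
        mean_recall = float(np.mean(recalls))
        if mean_recall > best_recall:
            best_params, best_recall = params, mean_recall
    logger.info("grid search best mean recall %.4f with %s", best_recall, best_params)
    return best_params


def train_final_model(
    X: np.ndarray, y: np.ndarray, params: dict, seed: int = 0
) -> tuple[RandomForestClassifier, np.ndarray]:
    """Oversample the full training set, fit the forest, return it with its
    normalized impurity-based feature importances."""
    Xs, ys = adasyn_oversample(np.asarray(X, float), np.asarray(y, int),
                               k=params["adasyn_n_neighbors"],
                               seed=_child_seed(seed, 303))
    clf = _make_forest(params, _child_seed(seed, 404))
    clf.fit(Xs, ys)
    return clf, clf.feature_importances_


def cross_validated_metrics(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, np.ndarray, pd.DataFrame]:
    """Out-of-fold scores for every labeled gene plus accuracy / sensitivity /
    precision at the provisional 0.5 cut and the ROC sweep."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        oof[va] = _fold_fit_predict(X, y, tr, va, params, seed, fold)
    pred = (oof >= 0.5).astype(int)
    fpr, tpr, thr = roc_curve(y, oof)
    metrics = {
        "accuracy": float(accuracy_score(y, pred)),
        "sensitivity": float(recall_score(y, pred)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "roc_auc": float(auc(fpr, tpr)),
    }
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return metrics, oof, roc_points


def density_zero_threshold(
    neg_scores: np.ndarray,
    grid_step: float = 0.001,
    eps_frac: float = 1e-3,
) -> float:
    """Score at which the negative-class kernel density first vanishes.

    Gaussian KDE with Silverman bandwidth on the negative out-of-fold scores,
    evaluated on a [0, 1] grid; the threshold is the smallest grid point at or
    above the negative mode where the density falls below eps_frac times the
    peak density. Falls back to the 99.5th percentile when no point qualifies.
    """
    neg = np.asarray(neg_scores, dtype=float)
    if len(neg) < 10:
        raise ConfigurationError("need at least 10 negative scores for the "
                                 "density threshold")
    if np.ptp(neg) == 0:
        logger.warning("all negative scores identical; degenerate threshold")
        return float(min(neg[0] + grid_step, 1.0))
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    dens = gaussian_kde(neg, bw_method="silverman")(grid)
    mode = grid[int(np.argmax(dens))]
    eligible = (grid >= mode) & (dens < eps_frac * dens.max())
    if eligible.any():
        return float(np.clip(grid[np.argmax(eligible)], 0.0, 1.0))
    logger.warning("density never vanishes on [0,1]; using 99.5th percentile")
    return float(np.clip(np.percentile(neg, 99.5), 0.0, 1.0))


def group_importances(importances: pd.Series) -> dict:
    """Aggregate importances into the three feature families.

    Reports both the plain sum and the mean of squared importances x 10^3 per
    group (the published aggregate is ambiguous; both are labeled).
    """
    prefix_map = {"sc.": "sc_expression", "traj.": "trajectory",
                  "prop.": "gene_intrinsic"}
    groups: dict[str, list[float]] = {g: [] for g in prefix_map.values()}
    for name, value in importances.items():
        for prefix, group in prefix_map.items():
            if name.startswith(prefix):
                groups[group].append(float(value))
                break
        else:
            raise SchemaError(f"feature '{name}' not assignable to a group")
    out = {}
    for group, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        out[group] = {
            "sum": float(arr.sum()) if len(arr) else 0.0,
            "mean_square_x1000": float((arr**2).mean() * 1e3) if len(arr) else 0.0,
        }
    return out


def predict_all(
    clf: RandomForestClassifier,
    scaled: pd.DataFrame,
    classes: TrainingClasses,
    threshold: float,
    schema: list[str],
) -> tuple[pd.Series, list[str]]:
    """Score every gene; candidates are unlabeled genes above the threshold,
    ranked by descending score with lexicographic tie break."""
    if list(scaled.columns) != list(schema):
        missing = sorted(set(schema) - set(scaled.columns))
        extra = sorted(set(scaled.columns) - set(schema))
        raise SchemaError(
            f"feature schema mismatch; missing={missing} unexpected={extra}"
        )
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    scores = pd.Series(clf.predict_proba(scaled.to_numpy())[:, pos_col],
                       index=scaled.index, name="stigma_score")
    training = classes.all_training_genes
    cand = scores[(scores > threshold) & ~scores.index.isin(training)]
    order = sorted(cand.index, key=lambda g: (-cand[g], g))
    return scores, list(order)


@dataclass
class StigmaResults:
    """Fitted-model container: estimates, diagnostics and ranked predictions."""

    best_params: dict
    cv_metrics: dict
    roc_points: pd.DataFrame
    feature_importances: pd.Series
    group_importance: dict
    scores: pd.Series
    oof_scores: pd.Series
    threshold: float
    predicted_candidates: list[str]
    training_genes: set[str]
    feature_names: list[str]
    labels: pd.Series
    classifier: RandomForestClassifier
    scaling: object
    feature_blocks: str = "full"

    def summary(self) -> str:
        m = self.cv_metrics
        lines = [
            "STIGMA gene prioritization results",
            "=" * 46,
            f"feature blocks:        {self.feature_blocks}",
            f"features:              {len(self.feature_names)}",
            f"genes scored:          {len(self.scores)}",
            f"positive class:        {int((self.labels == 'positive').sum())}",
            f"negative class:        {int((self.labels == 'negative').sum())}",
            "-" * 46,
            f"CV accuracy:           {m['accuracy']:.4f}",
            f"CV sensitivity:        {m['sensitivity']:.4f}",
            f"CV precision:          {m['precision']:.4f}",
            f"CV ROC AUC:            {m['roc_auc']:.4f}",
            f"score threshold:       {self.threshold:.3f}",
            f"predicted candidates:  {len(self.predicted_candidates)}",
            "-" * 46,
            "group importances (sum):",
        ]
        for group, vals in self.group_importance.items():
            lines.append(f"  {group:<20} {vals['sum']:.4f}")
        lines.append("best hyperparameters: "
                     + ", ".join(f"{k}={v}" for k, v in self.best_params.items()))
        return "\n".join(lines)

    def write_ranked_genes(self, path) -> None:
        from .io_qc import write_ranked_genes

        write_ranked_genes(self, path)

    def save(self, path) -> None:
        """Persist a versioned container with a feature-schema hash."""
        import joblib

        payload = {
            "format_version": 1,
            "schema_hash": schema_hash(self.feature_names),
            "feature_names": self.feature_names,
            "classifier": self.classifier,
            "scaling": self.scaling,
            "threshold": self.threshold,
            "best_params": self.best_params,
            "training_genes": sorted(self.training_genes),
        }
        joblib.dump(payload, path)

    def plot_score_density(self, ax=None):
        """Score distributions of the training classes and the threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, color in (("positive", "C3"), ("negative", "C0")):
            vals = self.scores[self.labels == label]
            if len(vals) > 1 and np.ptp(vals.to_numpy()) > 0:
                kde = gaussian_kde(vals.to_numpy(), bw_method="silverman")
                xs = np.linspace(0, 1, 200)
                ax.plot(xs, kde(xs), color=color, label=label)
        ax.axvline(self.threshold, ls="--", color="k",
                   label=f"threshold {self.threshold:.3f}")
        ax.set_xlabel("score")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"],
                label=f"AUC {self.cv_metrics['roc_auc']:.4f}")
        ax.plot([0, 1], [0, 1], ls=":", color="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def schema_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


def load_model(path) -> dict:
    import joblib

    payload = joblib.load(path)
    if payload.get("schema_hash") != schema_hash(payload["feature_names"]):
        raise SchemaError("model container schema hash mismatch")
    return payload


class StigmaModel:
    """Disease-gene classifier over an assembled :class:`FeatureMatrix`.

    Use :meth:`from_annotated_matrix` to build the feature matrix from a
    normalized expression object, a gene-property table and training classes;
    ``fit`` executes the full pipeline and returns :class:`StigmaResults`.
    """

    def __init__(self, features: FeatureMatrix,
                 grid: HyperparameterGrid | None = None, folds: int = 5):
        if not (features.labels != "unlabeled").any():
            raise ConfigurationError("feature matrix carries no labeled genes")
        self.features = features
        self.grid = grid or HyperparameterGrid()
        self.folds = folds
        self.feature_blocks = "full"

    @classmethod
    def from_annotated_matrix(
        cls,
        am,
        props: pd.DataFrame | None,
        classes: TrainingClasses,
        feature_blocks: str = "full",
        pseudotime_mode: str = "precomputed",
        n_bins: int = 20,
        n_basis: int = 10,
        grid: HyperparameterGrid | None = None,
        folds: int = 5,
        seed: int = 0,
    ) -> "StigmaModel":
        """Assemble the feature matrix for the requested feature blocks.

        Modes: ``full`` (cluster + trajectory + properties), ``no_trajectory``
        (cluster + properties), ``cluster_only`` (cluster block alone) and
        ``pseudobulk_only`` (all-cells pseudo-bulk expression alone).
        """
        if feature_blocks not in FEATURE_BLOCK_MODES:
            raise ConfigurationError(
                f"unknown feature block mode '{feature_blocks}'; "
                f"choose from {FEATURE_BLOCK_MODES}"
            )
        from .io_qc import normalize

        if am.norm is None:
            am = normalize(am)
        if feature_blocks == "pseudobulk_only":
            cft = retain_expressed_genes(pseudobulk_features(am))
            fm = assemble_features(cft, classes=classes)
        else:
            cft = retain_expressed_genes(per_cluster_features(am))
            tft = None
            if feature_blocks == "full":
                tft = trajectory_features(
                    am, mode=pseudotime_mode, n_bins=n_bins,
                    basis=build_basis(n_basis=n_basis), seed=seed,
                )
            use_props = props if feature_blocks in ("full", "no_trajectory") else None
            fm = assemble_features(cft, tft=tft, props=use_props, classes=classes)
        model = cls(fm, grid=grid, folds=folds)
        model.feature_blocks = feature_blocks
        return model

    def fit(self, seed: int = 0, params: dict | None = None) -> StigmaResults:
        """Run imputation, scaling, hyperparameter search (unless ``params``
        is given), CV metrics, thresholding and genome-wide prediction."""
        fm = self.features
        imputed = iterative_impute(fm.data)
        labeled = fm.labels != "unlabeled"
        _, scaling = minmax_scale(imputed.loc[labeled])
        scaled_all = scaling.transform(imputed)
        X_lab = scaled_all.loc[labeled].to_numpy()
        y = (fm.labels[labeled] == "positive").astype(int).to_numpy()

        best_params = params or grid_search(X_lab, y, self.grid,
                                            folds=self.folds, seed=seed)
        cv_metrics, oof, roc_points = cross_validated_metrics(
            X_lab, y, best_params, folds=self.folds, seed=seed
        )
        oof_scores = pd.Series(oof, index=fm.data.index[labeled], name="oof_score")
        threshold = density_zero_threshold(oof[y == 0])

        clf, importances = train_final_model(X_lab, y, best_params, seed=seed)
        importances = pd.Series(importances, index=scaled_all.columns,
                                name="importance")
        classes = TrainingClasses(
            positive=set(fm.data.index[labeled][y == 1]),
            negative=set(fm.data.index[labeled][y == 0]),
        )
        scores, candidates = predict_all(clf, scaled_all, classes, threshold,
                                         schema=list(scaled_all.columns))
        return StigmaResults(
            best_params=best_params,
            cv_metrics=cv_metrics,
            roc_points=roc_points,
            feature_importances=importances,
            group_importance=group_importances(importances),
            scores=scores,
            oof_scores=oof_scores,
            threshold=threshold,
            predicted_candidates=candidates,
            training_genes=classes.all_training_genes,
            feature_names=list(scaled_all.columns),
            labels=fm.labels.copy(),
            classifier=clf,
            scaling=scaling,
            feature_blocks=self.feature_blocks,
        )


def ablation_run(
    am,
    props: pd.DataFrame | None,
    classes: TrainingClasses,
    mode: str,
    seed: int = 0,
    params: dict | None = None,
    grid: HyperparameterGrid | None = None,
    folds: int = 5,
    pseudotime_mode: str = "precomputed",
) -> StigmaResults:
    """Re-run the pipeline restricted to the named feature block(s).

    When ``params`` is supplied (e.g. the full model's selection) the grid
    search is skipped so metrics are comparable across modes.
    """
    model = StigmaModel.from_annotated_matrix(
        am, props, classes, feature_blocks=mode,
        pseudotime_mode=pseudotime_mode, grid=grid, folds=folds, seed=seed,
    )
    return model.fit(seed=seed, params=params)
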