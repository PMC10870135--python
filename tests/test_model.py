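import numpy as np
import pandas as pd
import pytest

import stigma
from stigma.errors import ConfigurationError, SchemaError
from stigma.model import _child_seed, load_model, schema_hash
from stigma.preprocessing import adasyn_oversample


def pairwise_concordance_auc(y, scores):
    """O(n^2) oracle: P(score_pos > score_neg), ties counted 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def make_separable(n_pos=40, n_neg=120, n_features=6, seed=0, gap=4.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(gap, 1, (n_pos, n_features)),
                   rng.normal(0, 1, (n_neg, n_features))])
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


class TestAssembleFeatures:
    def _tables(self, n_genes=6, clusters=("A", "B", "C")):
        rng = np.random.default_rng(51)
        genes = [f"g{i}" for i in range(n_genes)]
        cft = stigma.ClusterFeatureTable(
            genes=np.array(genes, dtype=object), clusters=list(clusters),
            mean=rng.uniform(0, 2, (n_genes, len(clusters))),
            variance=rng.uniform(0, 1, (n_genes, len(clusters))),
            frac_expressing=rng.uniform(0, 1, (n_genes, len(clusters))),
            log_fc=rng.normal(0, 1, (n_genes, len(clusters))),
        )
        tft = stigma.TrajectoryFeatureTable(
            genes=np.array(genes, dtype=object), clusters=list(clusters),
            coefficients=rng.normal(0, 1, (n_genes, len(clusters), 10)),
        )
        props = pd.DataFrame(
            rng.uniform(0, 1, (n_genes, 9)),
            index=pd.Index(genes, name="gene"),
            columns=["pLI", "pRec", "pNull", "syn_z", "mis_z", "lof_z",
                     "gc_gene", "gc_promoter", "ortholog_confidence"],
        )
        classes = stigma.TrainingClasses(positive={"g0", "g1"},
                                         negative={"g2", "g3"})
        return cft, tft, props, classes

    def test_column_arithmetic(self):
        cft, tft, props, classes = self._tables()
        fm = stigma.assemble_features(cft, tft, props, classes)
        assert len(fm.feature_names) == 3 * 4 + 3 * 10 + 9  # == 51

    def test_gene_without_properties_has_missing_cells(self):
        cft, tft, props, classes = self._tables()
        fm = stigma.assemble_features(cft, tft, props.drop(index="g4"), classes)
        row = fm.data.loc["g4", [c for c in fm.feature_names
                                 if c.startswith("prop.")]]
        assert row.isna().all()

    def test_deterministic_assembly(self):
        cft, tft, props, classes = self._tables()
        a = stigma.assemble_features(cft, tft, props, classes)
        b = stigma.assemble_features(cft, tft, props, classes)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.feature_names == b.feature_names

    def test_no_labeled_genes_raises(self):
        cft, tft, props, _ = self._tables()
        classes = stigma.TrainingClasses(positive={"zz"}, negative={"yy"})
        with pytest.raises(ConfigurationError):
            stigma.assemble_features(cft, tft, props, classes)


class TestGridSearchAndForest:
    def test_singleton_grid_returned(self):
        X, y = make_separable(seed=1)
        grid = stigma.HyperparameterGrid(
            adasyn_n_neighbors=[5], n_estimators=[50], max_depth=[5],
            min_samples_split=[2], min_samples_leaf=[1])
        best = stigma.grid_search(X, y, grid, seed=1)
        assert best["n_estimators"] == 50

    def test_separable_data_perfect_recall(self):
        X, y = make_separable(seed=2)
        grid = stigma.HyperparameterGrid(
            adasyn_n_neighbors=[5], n_estimators=[50], max_depth=[5],
            min_samples_split=[2], min_samples_leaf=[1])
        params = stigma.grid_search(X, y, grid, seed=2)
        metrics, _, _ = stigma.cross_validated_metrics(X, y, params, seed=2)
        assert metrics["sensitivity"] == pytest.approx(1.0)

    def test_selection_matches_explicit_cv_oracle(self):
        # noisy, overlapping classes: a 1-tree forest vs a 100-tree forest
        X, y = make_separable(n_pos=60, n_neg=120, seed=3, gap=0.8)
        grid = stigma.HyperparameterGrid(
            adasyn_n_neighbors=[5], n_estimators=[1, 100], max_depth=[4],
            min_samples_split=[2], min_samples_leaf=[1])
        best = stigma.grid_search(X, y, grid, seed=3)
        # independent oracle: evaluate each setting with the same protocol
        from sklearn.metrics import recall_score
        from sklearn.model_selection import StratifiedKFold
        from sklearn.ensemble import RandomForestClassifier

        means = {}
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        for n_est in (1, 100):
            recalls = []
            for fold, (tr, va) in enumerate(skf.split(X, y)):
                Xs, ys = adasyn_oversample(X[tr], y[tr], k=5,
                                           seed=_child_seed(3, 101, fold))
                clf = RandomForestClassifier(
                    n_estimators=n_est, max_depth=4, min_samples_split=2,
                    min_samples_leaf=1, random_state=_child_seed(3, 202, fold),
                    n_jobs=1).fit(Xs, ys)
                pos = int(np.flatnonzero(clf.classes_ == 1)[0])
                pred = (clf.predict_proba(X[va])[:, pos] >= 0.5).astype(int)
                recalls.append(recall_score(y[va], pred))
            means[n_est] = np.mean(recalls)
        assert best["n_estimators"] == max(means, key=means.get)

    def test_importances_normalized_and_planted_signal_found(self):
        rng = np.random.default_rng(52)
        n = 200
        X = rng.normal(size=(n, 21))
        y = (X[:, 8] > 0).astype(int)
        params = dict(adasyn_n_neighbors=5, n_estimators=100, max_depth=6,
                      min_samples_split=2, min_samples_leaf=1)
        clf, imp = stigma.train_final_model(X, y, params, seed=4)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.argmax() == 8

    def test_balanced_oversampling_is_identity_in_cv(self):
        # with G=0 the oversampler returns its input, so out-of-fold scores
        # are identical to a manual run without any oversampling step
        X, y = make_separable(n_pos=60, n_neg=60, seed=5, gap=1.0)
        params = dict(adasyn_n_neighbors=5, n_estimators=30, max_depth=4,
                      min_samples_split=2, min_samples_leaf=1)
        _, oof, _ = stigma.cross_validated_metrics(X, y, params, seed=5)
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(5, shuffle=True, random_state=5)
        oof2 = np.full(len(y), np.nan)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            clf = RandomForestClassifier(
                n_estimators=30, max_depth=4, min_samples_split=2,
                min_samples_leaf=1, random_state=_child_seed(5, 202, fold),
                n_jobs=1).fit(X[tr], y[tr])
            pos = int(np.flatnonzero(clf.classes_ == 1)[0])
            oof2[va] = clf.predict_proba(X[va])[:, pos]
        np.testing.assert_allclose(oof, oof2, atol=1e-12)


class TestMetricsOracle:
    def test_auc_equals_pairwise_concordance(self):
        from sklearn.metrics import auc, roc_curve

        rng = np.random.default_rng(53)
        for _ in range(10):
            n = int(rng.integers(20, 80))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.uniform(size=n), 2)  # force ties
            fpr, tpr, _ = roc_curve(y, scores)
            assert auc(fpr, tpr) == pytest.approx(
                pairwise_concordance_auc(y, scores), abs=1e-9)

    def test_perfect_scores_metrics(self):
        X, y = make_separable(seed=6, gap=6.0)
        params = dict(adasyn_n_neighbors=5, n_estimators=60, max_depth=6,
                      min_samples_split=2, min_samples_leaf=1)
        metrics, oof, roc_points = stigma.cross_validated_metrics(
            X, y, params, seed=6)
        assert metrics["roc_auc"] == pytest.approx(1.0)
        assert metrics["precision"] == pytest.approx(1.0)
        assert (np.diff(roc_points["tpr"]) >= 0).all()

    def test_random_scores_auc_band(self):
        rng = np.random.default_rng(54)
        y = np.array([0, 1] * 100)
        scores = rng.uniform(size=200)
        assert 0.4 < pairwise_concordance_auc(y, scores) < 0.6


class TestDensityZeroThreshold:
    def test_concentrated_negatives(self):
        # concentrated near 0.1 with the largest scores at 0.3: the density
        # first vanishes a little beyond the observed maximum
        rng = np.random.default_rng(55)
        neg = np.concatenate([np.clip(rng.normal(0.1, 0.04, 280), 0, 0.25),
                              rng.uniform(0.2, 0.3, 19), [0.3]])
        thr = stigma.density_zero_threshold(neg)
        assert 0.3 < thr < 0.6

    def test_uniform_scores_trigger_fallback(self):
        rng = np.random.default_rng(56)
        neg = rng.uniform(0, 1, 500)
        thr = stigma.density_zero_threshold(neg)
        assert thr == pytest.approx(np.percentile(neg, 99.5), abs=1e-12)

    def test_degenerate_point_mass(self):
        thr = stigma.density_zero_threshold(np.full(50, 0.2))
        assert thr == pytest.approx(0.201)

    def test_nonincreasing_in_eps_frac(self):
        rng = np.random.default_rng(57)
        neg = np.clip(rng.normal(0.15, 0.08, 200), 0, 1)
        ts = [stigma.density_zero_threshold(neg, eps_frac=e)
              for e in (1e-4, 1e-3, 1e-2, 1e-1)]
        assert all(a >= b for a, b in zip(ts, ts[1:]))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            stigma.density_zero_threshold(np.arange(5) / 5)


class TestGroupImportances:
    def test_all_mass_on_one_expression_feature(self):
        imp = pd.Series({"sc.mean.A": 1.0, "traj.A.coef_0": 0.0,
                         "prop.pLI": 0.0})
        out = stigma.group_importances(imp)
        assert out["sc_expression"]["sum"] == 1.0
        assert out["trajectory"]["sum"] == 0.0

    def test_uniform_split(self):
        imp = pd.Series({f"sc.mean.c{i}": 0.02 for i in range(25)}
                        | {f"prop.f{i}": 0.02 for i in range(25)})
        out = stigma.group_importances(imp)
        assert out["sc_expression"]["sum"] == pytest.approx(0.5)
        assert out["gene_intrinsic"]["sum"] == pytest.approx(0.5)

    def test_unassignable_feature_raises(self):
        with pytest.raises(SchemaError):
            stigma.group_importances(pd.Series({"mystery": 1.0}))


class TestPredictAll:
    def _fitted(self):
        X, y = make_separable(seed=7)
        params = dict(adasyn_n_neighbors=5, n_estimators=40, max_depth=5,
                      min_samples_split=2, min_samples_leaf=1)
        clf, _ = stigma.train_final_model(X, y, params, seed=7)
        cols = [f"sc.mean.f{j}" for j in range(X.shape[1])]
        genes = [f"g{i:03d}" for i in range(len(X))]
        frame = pd.DataFrame(X, index=pd.Index(genes, name="gene"),
                             columns=cols)
        classes = stigma.TrainingClasses(positive=set(genes[:20]),
                                         negative=set(genes[40:60]))
        return clf, frame, classes

    def test_training_genes_excluded_from_candidates(self):
        clf, frame, classes = self._fitted()
        scores, candidates = stigma.predict_all(clf, frame, classes, 0.5,
                                                schema=list(frame.columns))
        assert scores.loc[sorted(classes.positive)[0]] > 0.9
        assert not set(candidates) & classes.all_training_genes

    def test_threshold_one_empty_candidates(self):
        clf, frame, classes = self._fitted()
        _, candidates = stigma.predict_all(clf, frame, classes, 1.0,
                                           schema=list(frame.columns))
        assert candidates == []

    def test_schema_mismatch_lists_columns(self):
        clf, frame, classes = self._fitted()
        with pytest.raises(SchemaError, match="sc.mean.f0"):
            stigma.predict_all(clf, frame.drop(columns="sc.mean.f0"), classes,
                               0.5, schema=list(frame.columns))


class TestModelPersistence:
    def test_save_load_round_trip_and_hash_guard(self, tmp_path, full_fit):
        path = tmp_path / "model.joblib"
        full_fit.save(path)
        payload = load_model(path)
        assert payload["feature_names"] == full_fit.feature_names
        assert payload["threshold"] == full_fit.threshold
        # tampering with the schema must be refused
        import joblib

        payload["feature_names"] = payload["feature_names"][:-1]
        joblib.dump(payload, path)
        with pytest.raises(SchemaError):
            load_model(path)

    def test_summary_mentions_key_quantities(self, full_fit):
        text = full_fit.summary()
        assert "ROC AUC" in text
        assert "threshold" in text
        assert schema_hash(full_fit.feature_names)  # stable, non-empty
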