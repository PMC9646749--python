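import numpy as np
import pandas as pd
import pytest

from lncid import schema
from lncid.model import (ModelBundle, ScalerStats, assemble_features,
                         build_hexamer_table_from_records, compute_metrics,
                         predict, rfecv_select, roc_auc, smote_balance,
                         train_pipeline, tune_and_train, zscore_apply,
                         zscore_fit, SMALL_GRID)
from lncid.struct_features import build_sass_tables

from oracles import auc_rank_oracle


@pytest.fixture(scope="module")
def tables(small_dataset):
    mrnas = [r for r in small_dataset if r.label == "mRNA"]
    lncs = [r for r in small_dataset if r.label == "lncRNA"]
    hexamer = build_hexamer_table_from_records(mrnas, lncs)
    sass = build_sass_tables(mrnas, lncs)
    return hexamer, sass


class TestSchema:
    def test_full_schema_size_and_blocks(self):
        assert len(schema.FULL_57) == 57
        assert len(schema.SIF_FEATURES) == 21
        assert len(schema.SSF_FEATURES) == 16
        assert len(schema.PF_FEATURES) == 20
        assert len(set(schema.FULL_57)) == 57

    def test_default_subset_composition(self):
        assert len(schema.TOP_28) == 28
        sif = [f for f in schema.TOP_28 if f in schema.SIF_FEATURES]
        ssf = [f for f in schema.TOP_28 if f in schema.SSF_FEATURES]
        pf = [f for f in schema.TOP_28 if f in schema.PF_FEATURES]
        assert (len(sif), len(ssf), len(pf)) == (14, 6, 8)

    def test_no_ssf_subset(self):
        assert len(schema.NO_SSF_22) == 22
        assert set(schema.NO_SSF_22) == set(schema.TOP_28) - set(schema.SSF_FEATURES)


class TestAssembleFeatures:
    def test_full_and_subset_column_counts(self, small_dataset, tables):
        hexamer, sass = tables
        recs = small_dataset[:5]
        full = assemble_features(recs, hexamer, sass)
        assert full.shape == (5, 57) and list(full.columns) == list(schema.FULL_57)
        top = assemble_features(recs, hexamer, sass, features=schema.TOP_28)
        assert top.shape == (5, 28)

    def test_identical_sequences_identical_rows(self, small_dataset, tables):
        hexamer, sass = tables
        rec = small_dataset[0]
        import copy
        twin = copy.deepcopy(rec)
        twin.id = "twin"
        X = assemble_features([rec, twin], hexamer, sass)
        np.testing.assert_array_equal(X.iloc[0].to_numpy(), X.iloc[1].to_numpy())

    def test_missing_structure_listed_in_error(self, small_dataset, tables):
        hexamer, sass = tables
        import copy
        rec = copy.deepcopy(small_dataset[0])
        rec.structure = None
        with pytest.raises(ValueError, match=rec.id):
            assemble_features([rec], hexamer, sass, with_structure=True)

    def test_structure_free_mode_zeroes_ssf(self, small_dataset, tables):
        hexamer, _ = tables
        X = assemble_features(small_dataset[:3], hexamer, None,
                              with_structure=False)
        assert (X[list(schema.SSF_FEATURES)].to_numpy() == 0).all()
        assert (X["orf_t0_length"] > 0).any()

    def test_threaded_extraction_bit_identical(self, small_dataset, tables):
        hexamer, sass = tables
        recs = small_dataset[:8]
        a = assemble_features(recs, hexamer, sass, threads=1)
        b = assemble_features(recs, hexamer, sass, threads=3)
        pd.testing.assert_frame_equal(a, b)


class TestZscore:
    def test_hand_computed_column(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        stats = zscore_fit(X)
        Z = zscore_apply(X, stats)
        np.testing.assert_allclose(Z["f"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        X = pd.DataFrame({"f": [5.0, 5.0, 5.0], "g": [1.0, 2.0, 3.0]})
        Z = zscore_apply(X, zscore_fit(X))
        assert (Z["f"] == 0).all()

    def test_train_statistics_applied_to_test(self, rng):
        train = pd.DataFrame(rng.normal(3, 2, size=(50, 4)), columns=list("abcd"))
        stats = zscore_fit(train)
        Z = zscore_apply(train, stats)
        np.testing.assert_allclose(Z.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(ddof=0), 1, atol=1e-9)
        test = pd.DataFrame(rng.normal(0, 1, size=(10, 4)), columns=list("abcd"))
        Zt = zscore_apply(test, stats)
        np.testing.assert_allclose(Zt.to_numpy(),
                                   (test.to_numpy() - stats.mean) / stats.std)


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_counts_equal_and_originals_preserved(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([0] * 45 + [1] * 15)
        Xb, yb = smote_balance(X, y, seed=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 45
        np.testing.assert_array_equal(Xb[:60], X)

    def test_identical_minority_points_yield_identical_synthetics(self):
        X = np.vstack([np.zeros((8, 2)), np.ones((2, 2)) * 7])
        y = np.array([0] * 8 + [1] * 2)
        Xb, yb = smote_balance(X, y, seed=3)
        synth = Xb[10:]
        assert (synth == 7).all()

    def test_synthetics_lie_on_minority_neighbor_segments(self, rng):
        """Post-hoc verification: every synthetic point is x + u (x_nn - x)
        for some minority x and one of its k nearest minority neighbors."""
        from sklearn.neighbors import NearestNeighbors
        k = 3
        X = rng.normal(size=(40, 2))
        y = np.array([0] * 30 + [1] * 10)
        Xb, yb = smote_balance(X, y, k_neighbors=k, seed=5)
        minority = X[y == 1]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
        idx = nn.kneighbors(minority, return_distance=False)[:, 1:]
        for s in Xb[40:]:
            on_segment = False
            for a, row in enumerate(minority):
                for b in idx[a]:
                    d = minority[b] - row
                    v = s - row
                    denom = float(d @ d)
                    if denom == 0:
                        if np.allclose(v, 0):
                            on_segment = True
                        continue
                    u = float(v @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(v, u * d, atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_small_minority_reduces_k_with_warning(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.warns(UserWarning):
            Xb, yb = smote_balance(X, y, k_neighbors=5, seed=0)
        assert (yb == 1).sum() == 9

    def test_seeded_reproducibility(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 22 + [1] * 8)
        X1, _ = smote_balance(X, y, seed=11)
        X2, _ = smote_balance(X, y, seed=11)
        np.testing.assert_array_equal(X1, X2)


class TestRfecv:
    def _planted(self, rng, n=240, informative=3, noise=7):
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, informative + noise))
        for j in range(informative):
            X[:, j] += (2.5 - 0.5 * j) * y
        cols = [f"signal_{j}" for j in range(informative)] + \
               [f"noise_{j}" for j in range(noise)]
        return pd.DataFrame(X, columns=cols), y

    def test_recovers_planted_signal(self, rng):
        X, y = self._planted(rng)
        params = {"n_estimators": 60, "max_depth": 3, "learning_rate": 0.3}
        selected, trace = rfecv_select(X, y, folds=3, seed=0,
                                       estimator_params=params)
        assert {"signal_0", "signal_1", "signal_2"} <= set(selected)

    def test_trace_has_one_point_per_size(self, rng):
        X, y = self._planted(rng, n=120, informative=2, noise=4)
        params = {"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3}
        _, trace = rfecv_select(X, y, folds=3, seed=0, estimator_params=params)
        assert [size for size, _ in trace] == list(range(6, 0, -1))

    def test_reproducible_under_fixed_seed(self, rng):
        X, y = self._planted(rng, n=120, informative=2, noise=4)
        params = {"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3}
        out1 = rfecv_select(X, y, folds=3, seed=4, estimator_params=params)
        out2 = rfecv_select(X, y, folds=3, seed=4, estimator_params=params)
        assert out1 == out2

    def test_single_feature_returned(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=60)})
        y = (X["only"] > 0).astype(int).to_numpy()
        selected, trace = rfecv_select(X, y, folds=3, seed=0)
        assert selected == ["only"] and len(trace) == 1


class TestTuneAndTrain:
    def test_separable_data_perfect_training_fit(self, rng):
        X = np.vstack([rng.normal(-4, 0.3, size=(40, 2)),
                       rng.normal(4, 0.3, size=(40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        clf, results = tune_and_train(X, y, folds=3, grid=SMALL_GRID, seed=0)
        assert (clf.predict(X) == y).all()
        assert len(results) == 2  # grid combinations evaluated

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            tune_and_train(rng.normal(size=(10, 2)), np.zeros(10), folds=2)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)
        clf1, r1 = tune_and_train(X, y, folds=3, grid=SMALL_GRID, seed=9)
        clf2, r2 = tune_and_train(X, y, folds=3, grid=SMALL_GRID, seed=9)
        assert r1 == r2
        np.testing.assert_array_equal(clf1.predict_proba(X), clf2.predict_proba(X))


class TestMetrics:
    def test_hand_evaluated_confusion(self):
        y = [1] * 100 + [0] * 100
        p = [1] * 98 + [0] * 2 + [0] * 97 + [1] * 3
        m = compute_metrics(y, p)
        assert (m.tp, m.fn, m.tn, m.fp) == (98, 2, 97, 3)
        assert m.sensitivity == pytest.approx(0.98)
        assert m.specificity == pytest.approx(0.97)
        assert m.precision == pytest.approx(0.9703, abs=1e-4)
        assert m.accuracy == pytest.approx(0.975)
        assert m.f_score == pytest.approx(0.9751, abs=1e-4)
        assert m.mcc == pytest.approx(0.9500, abs=1e-4)

    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.accuracy == m.mcc == m.f_score == 1.0

    def test_all_positive_on_balanced_data(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert m.sensitivity == 1.0 and m.specificity == 0.0 and m.mcc == 0.0
        assert m.degenerate

    def test_string_labels_accepted(self):
        m = compute_metrics(["lncRNA", "mRNA"], ["lncRNA", "mRNA"])
        assert m.accuracy == 1.0

    def test_accuracy_identity_and_f_harmonic_mean(self, rng):
        y = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        m = compute_metrics(y, p)
        assert m.accuracy == pytest.approx((m.tp + m.tn) / 200)
        if m.precision + m.sensitivity > 0:
            assert m.f_score == pytest.approx(
                2 * m.precision * m.sensitivity / (m.precision + m.sensitivity))

    def test_mcc_symmetric_under_class_swap(self, rng):
        y = rng.integers(0, 2, size=100)
        p = rng.integers(0, 2, size=100)
        m1 = compute_metrics(y, p)
        m2 = compute_metrics(1 - y, 1 - p)
        assert m1.mcc == pytest.approx(m2.mcc)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_inverted_scores(self):
        _, _, auc = roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == pytest.approx(0.0)

    def test_random_scores_near_half(self, rng):
        y = np.array([0] * 1000 + [1] * 1000)
        scores = rng.uniform(size=2000)
        _, _, auc = roc_auc(y, scores)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_equals_rank_statistic_oracle(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            scores = np.round(rng.uniform(size=50), 2)  # force some ties
            _, _, auc = roc_auc(y, scores)
            assert auc == pytest.approx(auc_rank_oracle(y, scores), abs=1e-9)


@pytest.fixture(scope="module")
def trained(small_dataset):
    bundle, report = train_pipeline(small_dataset, subset="top28",
                                    seed=5, folds=3, grid=SMALL_GRID)
    return bundle, report


class TestEndToEnd:
    def test_bundle_roundtrip_preserves_predictions(self, trained, small_dataset, tmp_path_factory):
        bundle, _ = trained
        out = tmp_path_factory.mktemp("bundle")
        bundle.save(out)
        loaded = ModelBundle.load(out)
        p1, _ = predict(bundle, small_dataset[:10])
        p2, _ = predict(loaded, small_dataset[:10])
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_deterministic_retraining(self, small_dataset, trained):
        bundle, _ = trained
        bundle2, _ = train_pipeline(small_dataset, subset="top28",
                                    seed=5, folds=3, grid=SMALL_GRID)
        p1, _ = predict(bundle, small_dataset[:20])
        p2, _ = predict(bundle2, small_dataset[:20])
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_invariant_to_input_order(self, trained, small_dataset):
        bundle, _ = trained
        recs = small_dataset[:12]
        p_fwd, _ = predict(bundle, recs)
        p_rev, _ = predict(bundle, recs[::-1])
        np.testing.assert_allclose(p_fwd, p_rev[::-1], atol=1e-12)

    def test_confident_training_lncrna_scores_high(self, trained, small_dataset):
        bundle, _ = trained
        lncs = [r for r in small_dataset if r.label == "lncRNA"][:5]
        probs, labels = predict(bundle, lncs)
        assert (probs > 0.5).mean() >= 0.8

    def test_structure_free_bundle_ignores_structures(self, small_dataset):
        bundle, _ = train_pipeline(small_dataset, subset="no-ssf22",
                                   seed=5, folds=3, grid=SMALL_GRID)
        import copy
        recs = [copy.deepcopy(r) for r in small_dataset[:8]]
        p1, _ = predict(bundle, recs)
        for r in recs:
            r.structure = None
            r.mfe = None
        p2, _ = predict(bundle, recs)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_cds_errors(self, small_dataset):
        import copy
        mrnas = [r for r in small_dataset if r.label == "mRNA"][:10]
        lncs = [r for r in small_dataset if r.label == "lncRNA"][:10]
        recs = [copy.deepcopy(r) for r in mrnas + lncs]
        broken = [r for r in recs if r.label == "mRNA"][0]
        broken.cds = None
        with pytest.raises(ValueError, match=broken.id):
            train_pipeline(recs, seed=0, folds=2, grid=SMALL_GRID)
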