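import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcadepth import (Mask, SVMModel, SVMRFE, dice, hard_segment,
                      probability_map, rfe_rank, sample_training_voxels,
                      select_optimal, soft_boundary, train_svm)
from bcadepth.classifier import ProbabilityMap, _svm_pipeline


@pytest.fixture(scope="module")
def planted_signal():
    """10 columns, exactly 2 (indices 3 and 7) carry class signal."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(200, 10))
    y = (X[:, 3] + X[:, 7] > 0).astype(int)
    return X, y


class TestTrainSVM:
    def test_separable_toy_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, (40, 2)) + [2, 0],
                       rng.normal(0, 0.2, (40, 2)) - [2, 0]])
        y = np.r_[np.ones(40), np.zeros(40)].astype(int)
        model = train_svm(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        m1, m2 = train_svm(X, y), train_svm(X, 1 - y)
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=5e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((10, 2)), np.ones(10))

    def test_json_round_trip_preserves_probabilities(self, planted_signal):
        X, y = planted_signal
        model = train_svm(pd.DataFrame(X), y)
        back = SVMModel.from_json(model.to_json())
        np.testing.assert_allclose(back.predict_proba(pd.DataFrame(X)),
                                   model.predict_proba(pd.DataFrame(X)),
                                   atol=1e-10)

    def test_heldout_phantom_auc(self, default_truth, second_truth, extractor):
        """Tumor/wall voxels from one phantom train a model that separates
        a second phantom's voxels (AUC > 0.95), cross-checked against the
        best univariate intensity threshold."""
        from scipy.stats import mannwhitneyu

        tum, wal = sample_training_voxels(default_truth, 200, seed=0)
        Xtr = extractor.extract(default_truth.volume, np.vstack([tum, wal]))
        ytr = np.r_[np.ones(len(tum)), np.zeros(len(wal))].astype(int)
        model = train_svm(Xtr, ytr)

        tum2, wal2 = sample_training_voxels(second_truth, 150, seed=1)
        Xte = extractor.extract(second_truth.volume, np.vstack([tum2, wal2]))
        yte = np.r_[np.ones(len(tum2)), np.zeros(len(wal2))].astype(int)
        p = model.predict_proba(Xte)
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score(yte, p)
        assert auc > 0.95
        # univariate oracle: the raw-intensity threshold already separates,
        # and the trained model does at least as well
        vol = second_truth.volume.data
        u = mannwhitneyu(vol[tuple(tum2.T)], vol[tuple(wal2.T)]).statistic
        auc_univ = max(u, len(tum2) * len(wal2) - u) / (len(tum2) * len(wal2))
        assert auc >= auc_univ - 0.02


def _exhaustive_best_pair(X, y):
    """Best 2-column subset by training accuracy (brute force oracle)."""
    best, best_acc = None, -1.0
    for pair in itertools.combinations(range(X.shape[1]), 2):
        pipe = _svm_pipeline(1.0).fit(X[:, pair], y)
        acc = (pipe.predict(X[:, pair]) == y).mean()
        if acc > best_acc:
            best, best_acc = pair, acc
    return set(best)


class TestRFE:
    def test_noise_column_eliminated_first(self):
        rng = np.random.default_rng(3)
        x0 = rng.normal(size=200)
        X = np.column_stack([x0, -x0 + 0.05 * rng.normal(size=200),
                             rng.normal(size=200)])
        y = (x0 > 0).astype(int)
        ranking = rfe_rank(X, y, step=1)
        assert ranking[-1] == 2

    def test_duplicate_informative_columns(self):
        rng = np.random.default_rng(4)
        x0 = rng.normal(size=200)
        X = np.column_stack([x0, x0, rng.normal(size=200)])
        y = (x0 > 0).astype(int)
        assert rfe_rank(X, y, step=1)[-1] == 2

    def test_ranking_is_permutation(self, planted_signal):
        X, y = planted_signal
        ranking = rfe_rank(X, y, step=1)
        assert sorted(ranking) == list(range(10))

    def test_top2_matches_exhaustive_search(self, planted_signal):
        X, y = planted_signal
        assert set(rfe_rank(X, y, step=1)[:2]) == _exhaustive_best_pair(X, y)

    def test_matches_sklearn_rfe(self, planted_signal):
        """Independent cross-check against sklearn's RFE on standardized
        data (same elimination criterion, |w| of a linear SVM)."""
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        X, y = planted_signal
        Xs = (X - X.mean(0)) / X.std(0)
        sk = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=2,
                 step=1).fit(Xs, y)
        assert set(np.flatnonzero(sk.support_)) == set(rfe_rank(X, y)[:2])

    def test_invalid_step_rejected(self, planted_signal):
        X, y = planted_signal
        with pytest.raises(ValueError):
            rfe_rank(X, y, step=10)


class TestSelectOptimal:
    def test_degenerate_grid(self, planted_signal):
        X, y = planted_signal
        ranking = rfe_rank(X, y, step=1)
        res = select_optimal(X, y, ranking, grid=[10])
        assert res.optimal_n == 10

    def test_cv_curve_peaks_at_two_signal_columns(self, planted_signal):
        X, y = planted_signal
        ranking = rfe_rank(X, y, step=1)
        res = select_optimal(X, y, ranking, folds=5,
                             grid=list(range(1, 11)), seed=0)
        assert res.optimal_n == 2
        # brute-force CV oracle with the same folds must agree
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        splits = list(skf.split(X, y))
        curve = []
        for N in range(1, 11):
            accs = [(_svm_pipeline(1.0)
                     .fit(X[np.ix_(tr, ranking[:N])], y[tr])
                     .predict(X[np.ix_(te, ranking[:N])]) == y[te]).mean()
                    for tr, te in splits]
            curve.append(np.mean(accs))
        np.testing.assert_allclose(res.cv_accuracy_curve, curve, atol=1e-12)

    def test_deterministic_given_seed(self, planted_signal):
        X, y = planted_signal
        ranking = rfe_rank(X, y, step=1)
        r1 = select_optimal(X, y, ranking, grid=[2, 5, 10], seed=3)
        r2 = select_optimal(X, y, ranking, grid=[2, 5, 10], seed=3)
        np.testing.assert_array_equal(r1.cv_accuracy_curve, r2.cv_accuracy_curve)
        assert r1.optimal_n == r2.optimal_n

    def test_reports_training_metrics(self, planted_signal):
        X, y = planted_signal
        res = select_optimal(X, y, rfe_rank(X, y), grid=[2])
        for v in (res.sensitivity, res.specificity, res.accuracy, res.auc):
            assert 0.8 <= v <= 1.0

    def test_estimator_interface(self, planted_signal):
        from sklearn.base import clone
        X, y = planted_signal
        est = SVMRFE(step=1, grid=list(range(1, 11)), seed=0)
        clone(est)  # sklearn param contract
        est.fit(pd.DataFrame(X), y)
        assert est.n_features_ == 2
        assert est.support_.sum() == 2
        assert est.transform(pd.DataFrame(X)).shape == (200, 2)
        proba = est.predict_proba(pd.DataFrame(X))
        assert proba.shape == (200, 2)
        np.testing.assert_allclose(proba.sum(1), 1.0)


class TestProbability:
    def test_monotone_along_weight_direction(self):
        # noisy labels keep the Platt sigmoid shallow, so monotonicity is
        # visible away from saturation
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 5))
        y = ((X[:, 0] + rng.normal(0, 1.5, 300)) > 0).astype(int)
        model = train_svm(X, y)
        scaler = model.pipeline.named_steps["scale"]
        w = model.weights
        pts = X.mean(0) + np.outer(np.linspace(-2, 2, 13), w * scaler.scale_)
        p = model.predict_proba(pts)
        assert np.all(np.diff(p) > 0)
        assert p.min() >= 0 and p.max() <= 1

    def test_column_mismatch_named(self, planted_signal):
        X, y = planted_signal
        cols = [f"f{i}" for i in range(10)]
        model = train_svm(pd.DataFrame(X, columns=cols), y)
        bad = pd.DataFrame(X, columns=cols[:-1] + ["other"])
        with pytest.raises(ValueError, match="other"):
            model.predict_proba(bad)


def _pmap(prob, dom):
    return ProbabilityMap(prob, Mask.from_bool(dom))


class TestSegmentation:
    def test_keeps_largest_component_only(self):
        dom = np.ones((12, 12, 6), bool)
        prob = np.zeros(dom.shape)
        prob[1:6, 1:6, 1:5] = 0.9     # 100 voxels
        prob[9:11, 9:11, 1:3] = 0.9   # small blob
        hard = hard_segment(_pmap(prob, dom))
        assert hard.bool()[2, 2, 2]
        assert not hard.bool()[9, 9, 1]

    def test_interior_hole_filled(self):
        dom = np.ones((9, 9, 9), bool)
        prob = np.zeros(dom.shape)
        prob[2:7, 2:7, 2:7] = 1.0
        prob[4, 4, 4] = 0.0
        hard = hard_segment(_pmap(prob, dom))
        assert hard.bool()[4, 4, 4]

    def test_empty_result_warns(self):
        dom = np.ones((4, 4, 4), bool)
        with pytest.warns(UserWarning):
            hard = hard_segment(_pmap(np.zeros(dom.shape), dom))
        assert hard.bool().sum() == 0

    def test_soft_boundary_empty_when_saturated(self):
        dom = np.ones((4, 4, 4), bool)
        prob = np.zeros(dom.shape)
        prob[:2] = 1.0
        assert soft_boundary(_pmap(prob, dom)).bool().sum() == 0

    def test_soft_boundary_full_interval_covers_domain(self):
        dom = np.zeros((4, 4, 4), bool)
        dom[1:3] = True
        prob = np.random.default_rng(0).random(dom.shape) * dom
        soft = soft_boundary(_pmap(prob, dom), lo=0.0, hi=1.0)
        np.testing.assert_array_equal(soft.bool(), dom)

    def test_bad_interval_rejected(self):
        dom = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError):
            soft_boundary(_pmap(np.zeros(dom.shape), dom), lo=0.9, hi=0.1)


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((6, 6, 6), bool)
        a[:3] = True
        b = ~a
        assert dice(Mask.from_bool(a), Mask.from_bool(a)) == 1.0
        assert dice(Mask.from_bool(a), Mask.from_bool(b)) == 0.0

    def test_partial_overlap_formula(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros_like(a)
        a.ravel()[:100] = True
        b.ravel()[20:120] = True     # overlap 80
        assert dice(Mask.from_bool(a), Mask.from_bool(b)) == pytest.approx(0.8)

    def test_both_empty_defined_as_one(self):
        e = Mask.from_bool(np.zeros((3, 3, 3), bool))
        assert dice(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(Mask.from_bool(np.zeros((3, 3, 3), bool)),
                 Mask.from_bool(np.zeros((4, 3, 3), bool)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 27 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) > 0.6
        b = rng.random((5, 5, 5)) > 0.6
        d1 = dice(Mask.from_bool(a), Mask.from_bool(b))
        d2 = dice(Mask.from_bool(b), Mask.from_bool(a))
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


def test_probability_map_scatter(default_truth, extractor):
    tum, wal = sample_training_voxels(default_truth, 60, seed=2)
    vox = np.vstack([tum, wal])
    X = extractor.extract(default_truth.volume, vox)
    y = np.r_[np.ones(len(tum)), np.zeros(len(wal))].astype(int)
    model = train_svm(X, y)
    dom = np.zeros_like(default_truth.tumor_mask.bool())
    dom[tuple(vox.T)] = True
    pm = probability_map(model, X, Mask.from_bool(dom))
    assert pm.prob.shape == dom.shape
    # confident interior tumor voxels score above 0.5
    assert np.median(pm.prob[tuple(tum.T)]) > 0.5
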