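"""Windowing, subject-aware splits, standardization, evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from gazestate.state_classifier import (
    AlignmentError,
    FoldReport,
    Hyperparams,
    build_dataset,
    build_windows,
    evaluate,
    interpolate_align,
    loso_folds,
    run_loso,
    standardize,
    summarize_runs,
)


class TestInterpolateAlign:
    def test_longest_series_unchanged(self):
        a = np.arange(10.0).reshape(-1, 1)
        b = np.arange(4.0).reshape(-1, 1)
        out = interpolate_align([a, b])
        assert np.array_equal(out[0], a)
        assert len(out[1]) == 10

    def test_linear_stretch_closed_form(self):
        out = interpolate_align([np.array([[0.0], [10.0]]),
                                 np.array([[0.0], [1.0], [2.0]])])
        assert np.allclose(out[0].ravel(), [0.0, 5.0, 10.0])

    def test_constant_series_stays_constant(self):
        out = interpolate_align([np.full((3, 2), 7.0), np.zeros((9, 2))])
        assert np.allclose(out[0], 7.0)

    def test_single_point_rejected(self):
        with pytest.raises(AlignmentError):
            interpolate_align([np.zeros((1, 2)), np.zeros((5, 2))])


class TestBuildWindows:
    def test_window_count_arithmetic(self):
        f = np.zeros((100, 4))
        X, y, g = build_windows(f, label=1, participant_id="P01", T=10)
        assert X.shape == (91, 10, 4)
        assert (y == 1).all() and (g == "P01").all()

    def test_boundary_single_window(self):
        X, _, _ = build_windows(np.zeros((10, 4)), 0, "P", T=10)
        assert X.shape[0] == 1

    def test_short_session_skipped(self):
        X, _, _ = build_windows(np.zeros((5, 4)), 0, "P", T=10)
        assert X.shape[0] == 0

    def test_windows_never_mix_participants(self, small_dataset):
        X, y, g = build_dataset(small_dataset, T=10)
        # each session contributes exactly L-T+1 windows with one pid
        per_session = len(small_dataset[0].metrics) - 10 + 1
        assert len(X) == len(small_dataset) * per_session
        for pid in set(g):
            assert len(set(y[g == pid])) == 3  # all three states per participant


class TestStandardize:
    def test_train_set_zscored(self):
        rng = np.random.default_rng(0)
        Xtr = rng.normal(5.0, 3.0, size=(50, 10, 4))
        (Ztr,) = standardize(Xtr)
        assert np.allclose(Ztr.mean(axis=(0, 1)), 0.0, atol=1e-9)
        assert np.allclose(Ztr.std(axis=(0, 1)), 1.0, atol=1e-9)

    def test_test_window_at_train_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        Xtr = rng.normal(2.0, 1.0, size=(40, 5, 3))
        mu = Xtr.mean(axis=(0, 1))
        Xte = np.broadcast_to(mu, (1, 5, 3)).copy()
        _, Zte = standardize(Xtr, Xte)
        assert np.allclose(Zte, 0.0, atol=1e-9)

    def test_shift_property(self):
        rng = np.random.default_rng(2)
        Xtr = rng.normal(size=(30, 4, 2))
        Xte = rng.normal(size=(10, 4, 2))
        sd = Xtr.std(axis=(0, 1))
        _, Z1 = standardize(Xtr, Xte)
        _, Z2 = standardize(Xtr, Xte + 1.0)
        assert np.allclose(Z2 - Z1, 1.0 / sd, atol=1e-9)

    def test_zero_variance_channel_centered(self):
        Xtr = np.random.default_rng(3).normal(size=(20, 5, 2))
        Xtr[:, :, 1] = 4.0
        (Ztr,) = standardize(Xtr)
        assert np.allclose(Ztr[:, :, 1], 0.0)


class TestLosoFolds:
    def test_partition_no_overlap(self, small_dataset):
        X, y, g = build_dataset(small_dataset, T=10)
        folds = loso_folds(g)
        assert len(folds) == 8
        all_test = np.concatenate([te for _, te, _ in folds])
        assert sorted(all_test) == list(range(len(X)))
        for tr, te, pid in folds:
            assert set(g[tr]) & set(g[te]) == set()
            assert set(g[te]) == {pid}

    def test_fold_standardization_differs(self, small_dataset):
        X, _, g = build_dataset(small_dataset, T=10)
        folds = loso_folds(g)
        mus = [X[tr].mean(axis=(0, 1)) for tr, _, _ in folds[:3]]
        assert not np.allclose(mus[0], mus[1])


class _ConstProba:
    def __init__(self, probs):
        self._p = probs

    def predict_proba(self, X):
        return self._p


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y]
        rep = evaluate(_ConstProba(probs), np.zeros((6, 2, 2)), y, "P")
        assert rep.accuracy == 100.0
        assert rep.f1_macro == 100.0
        assert np.trace(rep.confusion) == 6

    def test_chance_auc_with_uniform_scores(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 400)
        probs = rng.dirichlet(np.ones(3), size=1200)
        rep = evaluate(_ConstProba(probs), np.zeros((1200, 1, 1)), y)
        assert rep.auc_macro == pytest.approx(50.0, abs=5.0)

    def test_confusion_matrix_arithmetic(self):
        # hand-built: true 0 predicted [0,0,1]; true 1 predicted [1,1,2]; ...
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        pred = np.array([0, 0, 1, 1, 1, 2, 2, 2, 0])
        probs = np.eye(3)[pred] * 0.9 + 0.05
        probs /= probs.sum(axis=1, keepdims=True)
        rep = evaluate(_ConstProba(probs), np.zeros((9, 1, 1)), y)
        assert rep.confusion.tolist() == [[2, 1, 0], [0, 2, 1], [1, 0, 2]]
        # per-class precision = 2/3 everywhere by construction
        assert np.allclose(rep.per_class["precision"], 100 * 2 / 3)
        assert rep.accuracy == pytest.approx(100 * 6 / 9)
        # accuracy recomputed from the confusion matrix is identical
        assert rep.accuracy == pytest.approx(
            100 * np.trace(rep.confusion) / rep.confusion.sum(), abs=1e-10
        )

    def test_row_sums_equal_support(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        probs = np.full((6, 3), 1 / 3)
        rep = evaluate(_ConstProba(probs), np.zeros((6, 1, 1)), y)
        assert rep.confusion.sum(axis=1).tolist() == [2, 1, 3]


class TestRunLosoAndSummaries:
    def test_baselines_share_exact_folds(self, small_dataset):
        X, y, g = build_dataset(small_dataset, T=10)
        folds = loso_folds(g)[:2]
        hp = Hyperparams(seed=0)
        rf = run_loso(X, y, g, hp, model="rf", folds=folds)
        gbt = run_loso(X, y, g, hp, model="gbt", folds=folds)
        assert [r.participant_id for r in rf] == [r.participant_id for r in gbt]
        assert all(r.confusion.sum() == len(folds[i][1]) for i, r in enumerate(rf))

    def test_rf_deterministic(self, small_dataset):
        X, y, g = build_dataset(small_dataset, T=10)
        folds = loso_folds(g)[:1]
        hp = Hyperparams(seed=0)
        a = run_loso(X, y, g, hp, model="rf", folds=folds)[0]
        b = run_loso(X, y, g, hp, model="rf", folds=folds)[0]
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_summary_sd_convention(self):
        def rep(pid, acc):
            return FoldReport(
                participant_id=pid, accuracy=acc, f1_macro=acc, recall_macro=acc,
                precision_macro=acc, auc_macro=acc, loss=1.0,
                per_class=pd.DataFrame(
                    {"state": [0, 1, 2], "precision": [acc] * 3,
                     "recall": [acc] * 3, "f1": [acc] * 3, "support": [1, 1, 1]}
                ),
                confusion=np.eye(3, dtype=int),
            )

        res = summarize_runs([rep("A", 40.0), rep("B", 60.0)])
        assert res["summary"]["accuracy"]["mean"] == 50.0
        assert res["summary"]["accuracy"]["sd"] == pytest.approx(np.sqrt(200.0))
        single = summarize_runs([rep("A", 40.0)])
        assert single["summary"]["accuracy"]["sd"] == 0.0
        assert list(res["per_subject"]["accuracy"]) == [40.0, 60.0]

    def test_metrics_are_percentages(self, small_dataset):
        X, y, g = build_dataset(small_dataset, T=10)
        rep = run_loso(X, y, g, Hyperparams(seed=1), model="rf",
                       folds=loso_folds(g)[:1])[0]
        for v in (rep.accuracy, rep.f1_macro, rep.recall_macro, rep.auc_macro):
            assert 0.0 <= v <= 100.0
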