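import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from biomesite import classify, otu_table
from biomesite.classify import (HyperGrid, _best_f1_threshold, biased_subset,
                                confusion, f1_report,
                                feature_importance_overlap,
                                learning_curve_by_study, make_cv_plan,
                                mixture_auc, optimize_thresholds,
                                predict_labels, predict_proba, study_weights,
                                train_model)
from biomesite.mixtures import MixtureSpec, build_mixture_grid
from biomesite.otu_table import SampleMeta

SMALL_GRID = HyperGrid(n_trees=(30,), max_features_multipliers=(1.0,))


def meta_of(sites, studies=None):
    n = len(sites)
    studies = studies or ["st0"] * n
    return SampleMeta.from_arrays([f"s{i}" for i in range(n)], sites, studies)


@pytest.fixture(scope="module")
def small_model(small_dataset):
    _, table, meta, _ = small_dataset
    rel = otu_table.to_relative_abundance(table)
    plan = make_cv_plan(meta, outer_k=5, seed=0)
    train_ids, valid_ids = plan.fold_ids(0)
    model = train_model(rel[train_ids], meta.sites_for(train_ids),
                        grid=SMALL_GRID, inner_k=4, seed=0)
    return model, rel, meta, train_ids, valid_ids


class TestCvPlan:
    def test_exact_divisibility(self):
        meta = meta_of(sum([[c] * 20 for c in "abcde"], []))
        plan = make_cv_plan(meta, outer_k=5, seed=0)
        folds = pd.Series(plan.assignments)
        sites = meta.frame["body_site"]
        for f in range(5):
            in_fold = sites.loc[folds[folds == f].index]
            assert in_fold.value_counts().eq(4).all()

    def test_same_seed_identical(self):
        meta = meta_of(["a"] * 30 + ["b"] * 30)
        p1 = make_cv_plan(meta, seed=4)
        p2 = make_cv_plan(meta, seed=4)
        assert p1.assignments == p2.assignments

    def test_uneven_classes_within_one(self):
        meta = meta_of(sum([[c] * 7 for c in "abcde"], []))
        plan = make_cv_plan(meta, outer_k=5, seed=1)
        folds = pd.Series(plan.assignments)
        sites = meta.frame["body_site"]
        for f in range(5):
            counts = sites.loc[folds[folds == f].index].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_small_class_rejected_by_name(self):
        meta = meta_of(["a"] * 10 + ["rare"] * 3)
        with pytest.raises(ValueError, match="rare"):
            make_cv_plan(meta, outer_k=5)

    def test_folds_partition_samples(self):
        meta = meta_of(["a"] * 25 + ["b"] * 25)
        plan = make_cv_plan(meta, outer_k=5, seed=0)
        seen = set()
        for f in range(5):
            train, valid = plan.fold_ids(f)
            assert not set(train) & set(valid)
            seen |= set(valid)
        assert seen == set(meta.frame.index)


class TestTrainModel:
    def test_separable_classes_perfect_training_f1(self, rng):
        # disjoint OTU supports -> trivially separable
        counts = np.zeros((4, 20), dtype=int)
        counts[:2, :10] = rng.integers(50, 100, (2, 10))
        counts[2:, 10:] = rng.integers(50, 100, (2, 10))
        table = otu_table.OtuTable(counts, [f"o{i}" for i in range(4)],
                                   [f"s{j}" for j in range(20)])
        rel = otu_table.to_relative_abundance(table)
        labels = np.array(["x"] * 10 + ["y"] * 10)
        model = train_model(rel, labels, grid=SMALL_GRID, inner_k=4, seed=0)
        pred = predict_labels(model, rel)
        assert f1_report(pred, labels).mean_f1 == 1.0

    def test_grid_search_selects_and_reports(self, small_model):
        model, *_ = small_model
        assert model.hyperparameters["n_trees"] == 30
        assert 0.0 <= model.hyperparameters["inner_macro_f1"] <= 1.0

    def test_importances_sum_to_one(self, small_model):
        model, *_ = small_model
        assert model.importances.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        rel = pd.DataFrame(rng.random((3, 8)))
        with pytest.raises(ValueError, match="single class"):
            train_model(rel, ["x"] * 8, grid=SMALL_GRID)


class TestPredictProba:
    def test_rows_sum_to_one(self, small_model):
        model, rel, _, _, valid_ids = small_model
        proba = predict_proba(model, rel[valid_ids])
        np.testing.assert_allclose(proba.sum(axis=1).to_numpy(), 1.0, atol=1e-9)
        assert (proba.to_numpy() >= 0).all()

    def test_calibration_preserves_auc(self, small_model):
        # isotonic calibration is monotone, so the ranking and hence the AUC
        # of any one class's score is unchanged
        model, rel, meta, _, valid_ids = small_model
        X = rel[valid_ids]
        raw = model.forest.predict_proba(
            classify._align_features(model, X))
        raw = raw[:, [list(model.forest.classes_).index(c)
                      for c in model.classes]]
        cal = np.column_stack([model.calibrators[c].predict(raw[:, i])
                               for i, c in enumerate(model.classes)])
        cal = cal + 1e-9 * raw  # the rank-preserving tiebreak of predict_proba
        truth = meta.sites_for(valid_ids)
        for i, c in enumerate(model.classes):
            y = (truth == c).astype(int)
            if 0 < y.sum() < len(y) and len(np.unique(cal[:, i])) > 1:
                assert roc_auc_score(y, raw[:, i]) == pytest.approx(
                    roc_auc_score(y, cal[:, i]), abs=1e-9)

    def test_missing_features_imputed_zero(self, small_model):
        model, rel, _, _, valid_ids = small_model
        dropped = rel[valid_ids].iloc[:-5]
        proba = predict_proba(model, dropped)
        assert proba.shape == (len(valid_ids), len(model.classes))

    def test_no_overlap_rejected(self, small_model):
        model, rel, _, _, valid_ids = small_model
        alien = rel[valid_ids].copy()
        alien.index = [f"zz{i}" for i in range(len(alien))]
        with pytest.raises(ValueError, match="overlap"):
            predict_proba(model, alien)

    def test_heldout_prediction_mostly_correct(self, small_model):
        model, rel, meta, _, valid_ids = small_model
        pred = predict_labels(model, rel[valid_ids])
        rep = f1_report(pred, meta.sites_for(valid_ids))
        assert rep.mean_f1 > 0.7


class TestMetrics:
    def test_perfect_prediction(self):
        rep = f1_report(["a", "b"], ["a", "b"])
        assert rep.mean_f1 == 1.0 and set(rep.per_class_f1.values()) == {1.0}

    def test_hand_computed_example(self):
        rep = f1_report(["a", "b", "b", "b"], ["a", "a", "b", "b"])
        assert rep.per_class_f1["a"] == pytest.approx(2 / 3)
        assert rep.per_class_f1["b"] == pytest.approx(0.8)
        assert rep.mean_f1 == pytest.approx(0.73333, abs=1e-5)

    def test_equal_weights_match_unweighted(self):
        pred = ["a", "b", "b", "a"]
        true = ["a", "a", "b", "b"]
        unw = f1_report(pred, true)
        w = f1_report(pred, true, sample_weights=np.ones(4) * 0.25)
        assert w.per_class_f1 == pytest.approx(unw.per_class_f1)

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            f1_report(["a", "z"], ["a", "b"], classes=["a", "b"])

    def test_confusion_identity_and_rows(self):
        mat = confusion(["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(mat.to_numpy(), np.eye(3))

    def test_confusion_fractions(self):
        true = ["A"] * 9
        pred = ["B"] * 3 + ["A"] * 6
        mat = confusion(pred, true, classes=["A", "B"])
        assert mat.loc["A", "A"] == pytest.approx(2 / 3)
        assert mat.loc["A", "B"] == pytest.approx(1 / 3)

    def test_confusion_matches_pair_tally(self, rng):
        labels = list("abc")
        true = rng.choice(labels, 60)
        pred = rng.choice(labels, 60)
        mat = confusion(pred, true, classes=labels)
        for t in labels:
            n_t = np.sum(true == t)
            for p in labels:
                expected = np.sum((true == t) & (pred == p)) / n_t
                assert mat.loc[t, p] == pytest.approx(expected)


class TestStudyWeights:
    def test_single_study_uniform(self):
        w = study_weights(meta_of(["a"] * 4))
        assert (w == 0.25).all()

    def test_sizes_two_and_one(self):
        w = study_weights(meta_of(["a"] * 3, ["s1", "s1", "s2"]))
        np.testing.assert_allclose(w.to_numpy(), [0.5, 0.5, 1.0])

    def test_total_weight_equals_study_count(self, rng):
        studies = rng.choice(["s1", "s2", "s3", "s4"], 37)
        w = study_weights(meta_of(["a"] * 37, list(studies)))
        assert w.sum() == pytest.approx(len(set(studies)))


class TestThresholds:
    def test_separated_scores_pick_lowest_positive(self):
        t = _best_f1_threshold(np.array([0.9, 0.8]), np.array([0.1, 0.2]))
        assert t == pytest.approx(0.8)

    def test_brute_force_enumeration(self):
        pos = np.array([0.9, 0.6])
        neg = np.array([0.7, 0.2])
        # enumerate all candidate cuts by hand
        best = (-1.0, None)
        for t in sorted(set(np.concatenate([pos, neg])) |
                        {0.4, 0.65, 0.8}):  # midpoints
            tp = np.sum(pos >= t)
            fp = np.sum(neg >= t)
            fn = np.sum(pos < t)
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 >= best[0]:
                best = (f1, t)
        assert _best_f1_threshold(pos, neg) == pytest.approx(best[1])

    def test_threshold_table_complete_small_grid(self, small_model):
        model, rel, meta, train_ids, _ = small_model
        sub_meta = SampleMeta(meta.frame.loc[train_ids])
        fractions = [0.3, 0.6, 1.0]
        specs = [MixtureSpec("skin", "feces", f) for f in fractions] \
            + [MixtureSpec("feces", "skin", f) for f in fractions]
        rng = np.random.default_rng(0)
        counts = rel[train_ids] * 1000
        table = otu_table.OtuTable(counts.round().astype(int).to_numpy(),
                                   list(rel.index), train_ids)
        eval_sets = build_mixture_grid(table, sub_meta, specs, rng)
        tt = optimize_thresholds(model, eval_sets, table)
        assert len(tt) == 6
        for (t, b, f), thr in tt.thresholds.items():
            assert 0.0 <= thr <= 1.0

    def test_mixture_auc_bounds_and_signal(self, small_model):
        model, rel, meta, _, valid_ids = small_model
        sub_meta = SampleMeta(meta.frame.loc[valid_ids])
        counts = (rel[valid_ids] * 2000).round().astype(int).to_numpy()
        table = otu_table.OtuTable(counts, list(rel.index), valid_ids)
        rng = np.random.default_rng(3)
        es = build_mixture_grid(table, sub_meta,
                                [MixtureSpec("vagina", "feces", 0.2)], rng)[0]
        auc = mixture_auc(model, es, table)
        assert 0.5 <= auc <= 1.0

    def test_mixture_auc_empty_side_rejected(self, small_model):
        from biomesite.mixtures import MixedEvalSet
        model, rel, _, _, valid_ids = small_model
        counts = (rel[valid_ids] * 2000).round().astype(int).to_numpy()
        table = otu_table.OtuTable(counts, list(rel.index), valid_ids)
        es = MixedEvalSet(positives=[], negatives=valid_ids[:2],
                          spec=MixtureSpec("skin", "feces", 0.5))
        with pytest.raises(ValueError, match="empty"):
            mixture_auc(model, es, table)


class TestBiasedSubset:
    def _meta(self):
        sites = ["big"] * 100 + ["s1"] * 40 + ["s2"] * 40
        return meta_of(sites)

    def test_quota_is_ten_percent(self):
        ids = biased_subset(self._meta(), "big", ratio=0.1, seed=0)
        picked = pd.Series([self._meta().frame.loc[i, "body_site"] for i in ids])
        assert picked.value_counts()["big"] == 100
        assert picked.value_counts()["s1"] == 10
        assert picked.value_counts()["s2"] == 10

    def test_ratio_one_equal_sites_full_dataset(self):
        meta = meta_of(["a"] * 20 + ["b"] * 20)
        ids = biased_subset(meta, "a", ratio=1.0, seed=0)
        assert sorted(ids) == sorted(meta.frame.index)

    def test_seeded_repeatability(self):
        a = biased_subset(self._meta(), "big", seed=5)
        b = biased_subset(self._meta(), "big", seed=5)
        assert a == b

    def test_small_site_kept_whole(self, caplog):
        import logging
        meta = meta_of(["big"] * 100 + ["tiny"] * 4)
        with caplog.at_level(logging.WARNING):
            ids = biased_subset(meta, "big", ratio=0.1, seed=0)
        sites = [meta.frame.loc[i, "body_site"] for i in ids]
        assert sites.count("tiny") == 4


class TestLearningCurveAndOverlap:
    def test_curve_length_and_first_point(self, small_dataset):
        _, table, meta, _ = small_dataset
        rel = otu_table.to_relative_abundance(table)
        plan = make_cv_plan(meta, outer_k=5, seed=0)
        train_ids, valid_ids = plan.fold_ids(0)
        curve = learning_curve_by_study(
            rel[train_ids], SampleMeta(meta.frame.loc[train_ids]),
            rel[valid_ids], SampleMeta(meta.frame.loc[valid_ids]),
            grid=SMALL_GRID, inner_k=2, seed=0)
        n_studies = meta.frame.loc[train_ids, "study_id"].nunique()
        assert len(curve) == n_studies
        assert curve.iloc[0]["n_studies"] == 1
        assert curve["n_samples"].is_monotonic_increasing
        assert curve.iloc[-1]["mean_f1"] > 0.5

    def test_overlap_with_self(self, small_model):
        model, *_ = small_model
        shared, a_only, b_only, rho = feature_importance_overlap(model, model)
        assert a_only == b_only == 0
        assert shared == int((model.importances > 0).sum())
        assert rho == pytest.approx(1.0)

    def test_disjoint_importances_undefined_rho(self, small_model):
        import copy
        model, *_ = small_model
        other = copy.copy(model)
        imp = model.importances.copy()
        nz = imp[imp > 0].index
        other.importances = imp.copy()
        other.importances[:] = 0.0
        other.importances[imp.index.difference(nz)[:1]] = 1.0
        shared, _, _, rho = feature_importance_overlap(model, other)
        assert shared == 0 and rho is None

    def test_counts_match_set_arithmetic(self, small_model):
        import copy
        model, *_ = small_model
        other = copy.copy(model)
        imp = model.importances.copy()
        imp.iloc[:10] = 0.0
        other.importances = imp / imp.sum()
        pa = set(model.importances[model.importances > 0].index)
        pb = set(other.importances[other.importances > 0].index)
        shared, a_only, b_only, _ = feature_importance_overlap(model, other)
        assert (shared, a_only, b_only) == (len(pa & pb), len(pa - pb),
                                            len(pb - pa))
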