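import itertools

import numpy as np
import pytest

from connpls import (LabelTable, make_folds, run_cv, classify_binary,
                     metric_pearson_r, metric_rmse, metric_auc,
                     run_estimation_sets, sweep, permute_labels)
from connpls.crossval import FoldPlan


class TestMakeFolds:
    def test_990_subjects_10_folds(self):
        plan = make_folds(990, 10, seed=0)
        assert np.all(plan.fold_sizes() == 99)
        for f in range(10):
            assert plan.train_indices(f).size == 891

    def test_leave_one_out(self):
        plan = make_folds(7, 7, seed=1)
        assert np.all(plan.fold_sizes() == 1)

    def test_balanced_within_one(self):
        plan = make_folds(103, 10, seed=2)
        sizes = plan.fold_sizes()
        assert sizes.max() - sizes.min() <= 1

    def test_family_grouping_exhaustive_oracle(self):
        # families of sizes 3, 3, 4 into k=2 folds: among all assignments that
        # keep families whole, only {4} | {3,3} balances to 4/6, so greedy
        # descending-size placement must land exactly there
        family_id = np.repeat([0, 1, 2], [3, 3, 4])
        plan = make_folds(10, 2, seed=3, family_id=family_id)
        fold_of_family = [set(plan.assignment[family_id == f]) for f in range(3)]
        assert all(len(s) == 1 for s in fold_of_family)  # no family split
        best = min(
            (max(sizes) for sizes in
             ((sum(s for s, a in zip([3, 3, 4], assign) if a == 0),
               sum(s for s, a in zip([3, 3, 4], assign) if a == 1))
              for assign in itertools.product([0, 1], repeat=3))
             if all(sizes)),
        )
        assert plan.fold_sizes().max() == best == 6

    def test_grouped_never_splits_families(self):
        rng = np.random.default_rng(4)
        sizes = rng.integers(1, 6, size=30)
        family_id = np.repeat(np.arange(30), sizes)
        plan = make_folds(int(sizes.sum()), 10, seed=4, family_id=family_id)
        for f in range(30):
            assert len(set(plan.assignment[family_id == f])) == 1

    def test_k_exceeding_family_count(self):
        with pytest.raises(ValueError, match="families"):
            make_folds(10, 5, seed=0, family_id=np.repeat([0, 1, 2], [4, 3, 3]))

    def test_every_subject_in_exactly_one_fold(self):
        plan = make_folds(57, 5, seed=5)
        seen = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert np.array_equal(np.sort(seen), np.arange(57))


class TestMetrics:
    def test_identity(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert metric_pearson_r(y, y) == pytest.approx(1.0)
        assert metric_rmse(y, y) == 0.0

    def test_hand_computed_r_and_rmse(self):
        actual = [1.0, 2.0, 3.0]
        est = [1.0, 2.0, 4.0]
        assert metric_pearson_r(actual, est) == pytest.approx(9 / np.sqrt(84),
                                                              abs=1e-12)
        assert metric_rmse(actual, est) == pytest.approx(np.sqrt(1 / 3),
                                                         abs=1e-12)

    def test_auc_extremes_and_ties(self):
        y = np.array([0, 0, 1, 1], float)
        assert metric_auc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert metric_auc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0
        assert metric_auc(y, [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_r_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            metric_pearson_r([1, 1, 1], [1, 2, 3])

    def test_classify_binary_threshold(self):
        out = classify_binary([0.5, 0.49, -0.2, 1.7])
        assert out.tolist() == [1, 0, 0, 1]
        with pytest.raises(ValueError):
            classify_binary([np.nan])


class TestLabelTable:
    def test_missing_values_rejected_naming_subject(self):
        vals = np.array([[1.0, 0.0], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="sub0001"):
            LabelTable(vals, names=["a", "b"], kinds=["continuous", "binary"],
                       subject_ids=["sub0000", "sub0001"])

    def test_binary_coding_enforced(self):
        vals = np.array([[1.0, 2.0], [2.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="binary"):
            LabelTable(vals, names=["a", "b"], kinds=["continuous", "binary"])

    def test_subset_preserves_kinds(self, demo_labels):
        sub = demo_labels.subset(["group", "score_a"])
        assert sub.names == ["group", "score_a"]
        assert sub.kinds == ["binary", "continuous"]
        with pytest.raises(KeyError):
            demo_labels.subset(["nope"])


class TestRunCV:
    def test_every_subject_predicted_once(self, demo_features, demo_labels,
                                          demo_folds):
        res = run_cv(demo_features, demo_labels, demo_folds, d=8)
        assert res.pooled_predictions.shape == demo_labels.values.shape
        assert np.all(np.isfinite(res.pooled_predictions))
        assert len(res.fold_models) == demo_folds.k

    def test_no_leakage_test_labels_never_seen(self, demo_features,
                                               demo_labels, demo_folds):
        res = run_cv(demo_features, demo_labels, demo_folds, d=8)
        # corrupt the labels of fold 0's test subjects and refit: predictions
        # for those subjects must be identical
        vals = demo_labels.values.copy()
        test0 = demo_folds.test_indices(0)
        vals[test0] += 1000.0
        corrupted = LabelTable(vals, names=list(demo_labels.names),
                               kinds=["continuous"] * demo_labels.n_labels,
                               subject_ids=list(demo_labels.subject_ids))
        res2 = run_cv(demo_features, corrupted, demo_folds, d=8)
        assert np.array_equal(res.pooled_predictions[test0],
                              res2.pooled_predictions[test0])

    def test_permuted_labels_give_null_accuracy(self, demo_features,
                                                demo_labels, demo_folds):
        shuffled = permute_labels(demo_labels, seed=99)
        res = run_cv(demo_features, shuffled, demo_folds, d=8)
        for nm, kind in zip(demo_labels.names, demo_labels.kinds):
            if kind == "continuous":
                assert abs(res.metrics[nm]["R"]) < 0.35

    def test_single_vs_multi_label_similar_accuracy(self, recovery_runs):
        feats = recovery_runs["features"]
        ltab = recovery_runs["labels"]
        folds = recovery_runs["folds"]
        multi = run_cv(feats, ltab, folds, d=10,
                       label_subset=["a", "b", "c"])
        for nm in ["a", "b", "c"]:
            single = run_cv(feats, ltab, folds, d=10, label_subset=[nm])
            assert abs(multi.metrics[nm]["R"] -
                       single.metrics[nm]["R"]) < 0.1

    def test_metrics_invariant_to_subject_order(self, demo_features,
                                                demo_labels, demo_folds):
        res = run_cv(demo_features, demo_labels, demo_folds, d=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(demo_labels.n_subjects)
        j = demo_labels.names.index("score_a")
        r = metric_pearson_r(demo_labels.values[perm, j],
                             res.pooled_predictions[perm, j])
        assert r == pytest.approx(res.metrics["score_a"]["R"], abs=1e-12)

    def test_d_too_large_for_training_fold(self, demo_features, demo_labels,
                                           demo_folds):
        with pytest.raises(ValueError, match="training-fold"):
            run_cv(demo_features, demo_labels, demo_folds, d=demo_folds.n)

    def test_summary_lists_all_labels(self, demo_features, demo_labels,
                                      demo_folds):
        s = run_cv(demo_features, demo_labels, demo_folds, d=8).summary()
        for nm in demo_labels.names:
            assert nm in s


class TestEstimationSets:
    def test_cardinality_and_shared_folds(self, demo_features, demo_labels,
                                          demo_folds):
        out = run_estimation_sets(demo_features, demo_labels,
                                  main_labels=["score_a", "score_b"],
                                  supp_labels=["score_c", "group"],
                                  folds=demo_folds, d=8)
        assert set(out) == {"set1", "set2", "set3", "set4:score_a",
                            "set4:score_b"}
        for res in out.values():
            assert np.array_equal(res.folds.assignment, demo_folds.assignment)

    def test_adding_labels_barely_changes_main_accuracy(self, demo_features,
                                                        demo_labels,
                                                        demo_folds):
        out = run_estimation_sets(demo_features, demo_labels,
                                  main_labels=["score_a", "score_b"],
                                  supp_labels=["score_c", "group"],
                                  folds=demo_folds, d=8)
        for nm in ["score_a", "score_b"]:
            assert abs(out["set1"].metrics[nm]["R"] -
                       out["set3"].metrics[nm]["R"]) < 0.1

    def test_unknown_label_rejected(self, demo_features, demo_labels,
                                    demo_folds):
        with pytest.raises(KeyError):
            run_estimation_sets(demo_features, demo_labels, ["bogus"],
                                ["score_a"], demo_folds, d=8)


class TestSweep:
    def test_shape_of_d_sweep(self, demo_features, demo_labels, demo_folds):
        tab = sweep(demo_features, demo_labels, axis="d", values=[5, 8, 10],
                    folds=demo_folds, label_subset=["score_a"])
        rvals = tab[(tab.metric == "R")]
        assert len(rvals) == 3
        assert set(rvals.variant) == {5, 8, 10}

    def test_missing_variant_rejected(self, demo_labels, demo_folds,
                                      demo_features):
        with pytest.raises(ValueError, match="missing features"):
            sweep({"full": demo_features}, demo_labels, axis="conn_method",
                  values=["full", "partial"], folds=demo_folds)

    def test_empty_values_rejected(self, demo_features, demo_labels):
        with pytest.raises(ValueError, match="non-empty"):
            sweep(demo_features, demo_labels, axis="d", values=[])


def test_fold_plan_rejects_empty_folds():
    with pytest.raises(ValueError):
        FoldPlan(k=3, assignment=np.array([0, 0, 1, 1]), grouped=False, seed=0)
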