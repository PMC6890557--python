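import numpy as np
import pytest

from connpls import (SimulationConfig, simulate_dataset, build_feature_matrix,
                     LabelTable, make_folds, run_permutation_test)


@pytest.fixture(scope="session")
def demo_dataset():
    """Small mixed-label cohort used across modules: 120 subjects, 15 ROIs."""
    cfg = SimulationConfig(n_subjects=120, n_rois=15, n_timepoints=200, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def demo_features(demo_dataset):
    return build_feature_matrix(demo_dataset.timeseries, method="partial",
                                subject_ids=demo_dataset.subject_ids)


@pytest.fixture(scope="session")
def demo_labels(demo_dataset):
    return LabelTable.from_dataset(demo_dataset)


@pytest.fixture(scope="session")
def demo_folds(demo_dataset):
    return make_folds(demo_dataset.n_subjects, k=5, seed=7)


@pytest.fixture(scope="session")
def calibration_pvalues():
    """Monte-Carlo accuracy p-values under the global null (labels decoupled
    from the brain): 200 independent cohorts of 150 subjects, 99 permutations
    each, three continuous labels -> array of shape (200, 3)."""
    reps = 200
    out = np.empty((reps, 3))
    for rep in range(reps):
        cfg = SimulationConfig(
            n_subjects=150, n_rois=15, n_timepoints=150, effect_size=0.0,
            seed=20_000 + rep,
            label_spec=(("a", "continuous"), ("b", "continuous"),
                        ("c", "continuous")))
        ds = simulate_dataset(cfg)
        feats = build_feature_matrix(ds.timeseries, method="partial")
        folds = make_folds(150, k=5, seed=rep)
        pr = run_permutation_test(feats, LabelTable.from_dataset(ds), folds,
                                  d=5, n_perm=99, seed=rep,
                                  compute_weights=False)
        out[rep] = pr.p_accuracy
    return out


@pytest.fixture(scope="session")
def recovery_runs():
    """Strong planted effects: permutation runs (multi-label and single-label)
    against a 300-subject cohort with 10 effect edges per label."""
    cfg = SimulationConfig(
        n_subjects=300, n_rois=15, n_timepoints=400, n_effect_edges=10,
        effect_size=6.0, seed=101,
        label_spec=(("a", "continuous"), ("b", "continuous"),
                    ("c", "continuous")))
    ds = simulate_dataset(cfg)
    feats = build_feature_matrix(ds.timeseries, method="partial")
    ltab = LabelTable.from_dataset(ds)
    folds = make_folds(300, k=5, seed=3)
    multi = run_permutation_test(feats, ltab, folds, d=10, n_perm=199, seed=5)
    single = run_permutation_test(feats, ltab, folds, d=10, n_perm=199, seed=6,
                                  label_subset=["a"])
    return {"dataset": ds, "features": feats, "labels": ltab, "folds": folds,
            "multi": multi, "single": single}
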