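"""Cross-validated estimation protocol: folds, metrics, estimation sets, sweeps.

The evaluation protocol is k-fold cross-validation (default k = 10): subjects
are randomly partitioned into k near-equal subsets; each subset serves once as
the test set while a PLS model is fitted on the remaining subjects (training
means computed on training rows only), and its predictions for the held-out
subjects are pooled.  Performance per continuous label is the Pearson
correlation R between pooled predicted and actual values together with the
RMSE; binary labels are scored by thresholding the (numeric) estimate at 0.5
and reporting accuracy plus the rank-based AUC.

An optional grouped mode keeps families intact: no family identifier ever
spans two folds, so related subjects never straddle the training/testing
boundary.

Metrics are computed on predictions pooled across folds (one value per label
per experiment), and a fold plan is an explicit, reusable object so that
estimation sets, sweeps and permutation runs can share the identical
partition and differ only in the manipulated factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .connectivity import FeatureMatrix
from .pls import PLS, PLSResults, DEFAULT_D

__all__ = ["LabelTable", "FoldPlan", "CVResult", "make_folds", "run_cv",
           "classify_binary", "metric_pearson_r", "metric_rmse", "metric_auc",
           "run_estimation_sets", "sweep", "DEFAULT_K_FOLDS"]

DEFAULT_K_FOLDS = 10


@dataclass
class LabelTable:
    """Subjects x labels with per-label continuous/binary flags.

    Binary labels must be coded exactly {0, 1}; missing values are rejected
    at construction (subjects with incomplete labels are excluded upstream).
    """

    values: np.ndarray
    names: list
    kinds: list
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("label values must be 2-D (subjects x labels)")
        if not np.all(np.isfinite(self.values)):
            bad = np.flatnonzero(~np.all(np.isfinite(self.values), axis=1))
            ids = [self.subject_ids[i] if self.subject_ids else i for i in bad]
            raise ValueError(f"missing/non-finite labels for subject(s) {ids}")
        if len(self.names) != self.values.shape[1] or len(self.kinds) != len(self.names):
            raise ValueError("names/kinds length must match label count")
        unknown = set(self.kinds) - {"continuous", "binary"}
        if unknown:
            raise ValueError(f"unknown label kind(s) {unknown}")
        for j, kind in enumerate(self.kinds):
            if kind == "binary":
                vals = set(np.unique(self.values[:, j]))
                if not vals <= {0.0, 1.0}:
                    raise ValueError(
                        f"binary label {self.names[j]!r} must be coded "
                        f"{{0, 1}}, found values {sorted(vals)}")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_labels(self) -> int:
        return self.values.shape[1]

    def subset(self, names) -> "LabelTable":
        names = list(names)
        missing = [nm for nm in names if nm not in self.names]
        if missing:
            raise KeyError(f"unknown label name(s) {missing}")
        idx = [self.names.index(nm) for nm in names]
        return LabelTable(values=self.values[:, idx], names=names,
                          kinds=[self.kinds[i] for i in idx],
                          subject_ids=list(self.subject_ids))

    @classmethod
    def from_dataset(cls, dataset) -> "LabelTable":
        return cls(values=dataset.labels.copy(), names=list(dataset.label_names),
                   kinds=list(dataset.label_kinds),
                   subject_ids=list(dataset.subject_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.names)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every subject to exactly one of k test folds."""

    k: int
    assignment: np.ndarray
    grouped: bool
    seed: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        sizes = np.bincount(a, minlength=self.k)
        if a.min(initial=0) < 0 or a.max(initial=0) >= self.k or np.any(sizes == 0):
            raise ValueError("every fold id must be in [0, k) and non-empty")

    @property
    def n(self) -> int:
        return self.assignment.size

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(n: int, k: int = DEFAULT_K_FOLDS, seed: int = 0,
               family_id=None) -> FoldPlan:
    """Random balanced k-fold partition, optionally keeping families intact.

    Plain mode shuffles subjects and deals them round-robin, so fold sizes
    differ by at most one.  Grouped mode assigns whole families greedily —
    descending family size onto the currently smallest fold — so no family
    spans two folds (exact balance is then not guaranteed for large
    families).
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    if family_id is None:
        perm = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[perm] = np.arange(n) % k
        return FoldPlan(k=k, assignment=assignment, grouped=False, seed=seed)

    family_id = np.asarray(family_id)
    if family_id.size != n:
        raise ValueError("family_id length must equal n")
    fams, inverse = np.unique(family_id, return_inverse=True)
    if k > fams.size:
        raise ValueError(f"k={k} exceeds the number of families ({fams.size})")
    sizes = np.bincount(inverse)
    order = rng.permutation(fams.size)  # random tie-breaking within sizes
    order = order[np.argsort(-sizes[order], kind="stable")]
    fold_load = np.zeros(k, dtype=int)
    fam_fold = np.empty(fams.size, dtype=int)
    for f in order:
        tgt = int(np.argmin(fold_load))
        fam_fold[f] = tgt
        fold_load[tgt] += sizes[f]
    return FoldPlan(k=k, assignment=fam_fold[inverse], grouped=True, seed=seed)


# ---------------------------------------------------------------------------
# metrics

def metric_pearson_r(actual, estimated) -> float:
    actual = np.asarray(actual, float).ravel()
    estimated = np.asarray(estimated, float).ravel()
    if actual.size != estimated.size:
        raise ValueError("length mismatch")
    if actual.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if actual.std() == 0 or estimated.std() == 0:
        raise ValueError("zero variance input to Pearson correlation")
    return float(np.corrcoef(actual, estimated)[0, 1])


def metric_rmse(actual, estimated) -> float:
    actual = np.asarray(actual, float).ravel()
    estimated = np.asarray(estimated, float).ravel()
    if actual.size != estimated.size or actual.size == 0:
        raise ValueError("need equal, non-zero lengths")
    return float(np.sqrt(np.mean((actual - estimated) ** 2)))


def metric_auc(actual, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic; tied
    scores count one half."""
    actual = np.asarray(actual, float).ravel()
    scores = np.asarray(scores, float).ravel()
    if actual.size != scores.size:
        raise ValueError("length mismatch")
    if set(np.unique(actual)) != {0.0, 1.0}:
        raise ValueError("AUC needs both classes present, coded {0, 1}")
    return float(roc_auc_score(actual, scores))


def classify_binary(estimates) -> np.ndarray:
    """Threshold numeric estimates at 0.5: >= 0.5 -> 1, < 0.5 -> 0."""
    estimates = np.asarray(estimates, float)
    if not np.all(np.isfinite(estimates)):
        raise ValueError("non-finite estimate")
    return (estimates >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# cross-validated runs

@dataclass
class CVResult:
    """Pooled out-of-fold predictions and per-label metrics of one CV run.

    ``metrics`` maps label name to ``{"R": .., "RMSE": ..}`` for continuous
    labels and ``{"ACC": .., "AUC": ..}`` for binary ones; every subject is
    predicted exactly once and metrics are computed from the pooled
    predictions.
    """

    pooled_predictions: np.ndarray
    labels: LabelTable
    folds: FoldPlan
    fold_models: list
    metrics: dict
    config: dict

    def summary(self) -> str:
        lines = [
            "Cross-validated PLS estimation",
            "=" * 50,
            f"subjects: {self.labels.n_subjects}   folds: {self.folds.k}   "
            f"d: {self.config.get('d')}",
            "-" * 50,
            f"{'label':<16}{'kind':<12}{'metrics'}",
        ]
        for nm, kind in zip(self.labels.names, self.labels.kinds):
            mm = self.metrics[nm]
            txt = "  ".join(f"{k}={v:.4f}" for k, v in mm.items())
            lines.append(f"{nm:<16}{kind:<12}{txt}")
        return "\n".join(lines)

    def average_coefficients(self) -> np.ndarray:
        """Elementwise mean of the per-fold coefficient matrices (B-bar)."""
        from .permutation import average_B
        return average_B(self.fold_models)


def _score_predictions(pred: np.ndarray, labels: LabelTable) -> dict:
    metrics = {}
    for j, (nm, kind) in enumerate(zip(labels.names, labels.kinds)):
        y, yhat = labels.values[:, j], pred[:, j]
        if kind == "binary":
            metrics[nm] = {"ACC": float(np.mean(classify_binary(yhat) == y)),
                           "AUC": metric_auc(y, yhat)}
        else:
            metrics[nm] = {"R": metric_pearson_r(y, yhat),
                           "RMSE": metric_rmse(y, yhat)}
    return metrics


def run_cv(features: FeatureMatrix, labels: LabelTable, folds: FoldPlan,
           d: int = DEFAULT_D, label_subset=None, keep_models: bool = True,
           _splits=None) -> CVResult:
    """One cross-validated multi-response PLS run.

    Per fold, the model (including feature and label means) is fitted on
    training rows only and applied to the held-out rows; predictions are
    pooled in subject order.  ``label_subset`` restricts the Y block.
    ``_splits`` may carry precomputed (train, test) index pairs to avoid
    recomputation in tight permutation loops.
    """
    if labels.n_subjects != features.n_subjects:
        raise ValueError("features and labels have different subject counts")
    if folds.n != features.n_subjects:
        raise ValueError("fold plan does not match subject count")
    if label_subset is not None:
        labels = labels.subset(label_subset)
    X = features.values
    Y = labels.values
    pred = np.empty_like(Y)
    models: list[PLSResults] = []
    splits = (_splits if _splits is not None else
              [(folds.train_indices(f), folds.test_indices(f))
               for f in range(folds.k)])
    for train, test in splits:
        if d >= train.size:
            raise ValueError(f"d={d} must be smaller than the training-fold "
                             f"size {train.size}")
        res = PLS(Y[train], X[train]).fit(d=d)
        pred[test] = res.predict(X[test])
        if keep_models:
            models.append(res)
    return CVResult(pooled_predictions=pred, labels=labels, folds=folds,
                    fold_models=models, metrics=_score_predictions(pred, labels),
                    config={"d": d, "k": folds.k, "seed": folds.seed,
                            "labels": list(labels.names)})


def run_estimation_sets(features: FeatureMatrix, labels: LabelTable,
                        main_labels, supp_labels, folds: FoldPlan,
                        d: int = DEFAULT_D) -> dict:
    """The four estimation sets, sharing one fold plan for comparability.

    set1: all main labels jointly (multi-label); set2: all supplementary
    labels jointly; set3: main + supplementary jointly; set4: one
    single-label run per main label (keys ``"set4:<name>"``).
    """
    main_labels, supp_labels = list(main_labels), list(supp_labels)
    out = {
        "set1": run_cv(features, labels, folds, d=d, label_subset=main_labels),
        "set2": run_cv(features, labels, folds, d=d, label_subset=supp_labels),
        "set3": run_cv(features, labels, folds, d=d,
                       label_subset=main_labels + supp_labels),
    }
    for nm in main_labels:
        out[f"set4:{nm}"] = run_cv(features, labels, folds, d=d,
                                   label_subset=[nm])
    return out


def sweep(features_by_variant, labels: LabelTable, axis: str, values,
          folds: FoldPlan | None = None, d: int = DEFAULT_D,
          label_subset=None, k: int = DEFAULT_K_FOLDS,
          seed: int = 0) -> pd.DataFrame:
    """Re-run CV along one axis, everything else fixed; tidy long output.

    ``axis`` is one of ``"d"`` (``features_by_variant`` is a single
    FeatureMatrix), ``"roi_count"`` or ``"conn_method"`` (dict mapping each
    swept value to its FeatureMatrix).  Returns columns
    (variant, label, metric, value).
    """
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        if axis == "d":
            feats = features_by_variant
            d_run = int(v)
        elif axis in ("roi_count", "conn_method"):
            try:
                feats = features_by_variant[v]
            except (KeyError, TypeError):
                raise ValueError(f"missing features for variant {v!r}") from None
            d_run = d
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        plan = folds if folds is not None else make_folds(feats.n_subjects, k=k,
                                                          seed=seed)
        res = run_cv(feats, labels, plan, d=d_run, label_subset=label_subset,
                     keep_models=False)
        for nm, mm in res.metrics.items():
            for metric, val in mm.items():
                rows.append({"axis": axis, "variant": v, "label": nm,
                             "metric": metric, "value": val})
    return pd.DataFrame(rows)
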