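"""Permutation significance of estimation accuracies and of edge weights.

Significance is assessed non-parametrically by rerunning the identical
cross-validation pipeline after randomly shuffling the label rows (one joint
permutation of subjects across all labels, so inter-label correlation is
preserved under the null; the feature matrix and the fold plan are untouched).
With N permutations the p-value of an observed statistic is

    P = (1 + #exceedances) / (1 + N),

where an exceedance is a strictly greater permuted value: for per-label
accuracy, a permuted pooled correlation R exceeding the observed R (accuracy
for binary labels); for per-edge weights, a permuted fold-averaged absolute
coefficient |B_bar_ij| exceeding the observed one.  The smallest attainable
p-value is 1/(N + 1) — with N = 5000 (the pipeline default), 1/5001 = 0.0002.
Edges whose weight p-value is strictly below alpha (default 0.05) form the
significant-contribution mask; no multiple-testing correction is applied
across the edges-by-labels grid, so the mask is a raw-threshold set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .connectivity import FeatureMatrix
from .crossval import (LabelTable, FoldPlan, run_cv, DEFAULT_K_FOLDS)
from .pls import DEFAULT_D

__all__ = ["PermutationResult", "average_B", "perm_pvalue", "permute_labels",
           "run_permutation_test", "overlap_significant", "DEFAULT_N_PERM",
           "DEFAULT_ALPHA"]

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05


def average_B(models) -> np.ndarray:
    """Elementwise mean of the per-fold coefficient matrices."""
    models = list(models)
    if not models:
        raise ValueError("no models to average")
    shapes = {m.B.shape for m in models}
    if len(shapes) != 1:
        raise ValueError(f"coefficient shapes differ across folds: {shapes}")
    return np.mean([m.B for m in models], axis=0)


def perm_pvalue(n_stronger: int, n_perm: int) -> float:
    """(1 + n_stronger) / (1 + n_perm); never zero, at most one."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 <= n_stronger <= n_perm:
        raise ValueError(f"n_stronger must lie in [0, {n_perm}]")
    return (1 + n_stronger) / (1 + n_perm)


def permute_labels(labels: LabelTable, seed: int, joint: bool = True) -> LabelTable:
    """Shuffle label rows under the null of label-feature independence.

    Joint mode (default) applies one subject permutation to the whole label
    matrix, preserving inter-label correlation; ``joint=False`` shuffles each
    label column independently.
    """
    rng = np.random.default_rng(seed)
    n = labels.n_subjects
    if joint:
        vals = labels.values[rng.permutation(n)]
    else:
        vals = np.column_stack([labels.values[rng.permutation(n), j]
                                for j in range(labels.n_labels)])
    return LabelTable(values=vals, names=list(labels.names),
                      kinds=list(labels.kinds),
                      subject_ids=list(labels.subject_ids))


def _primary_stat(result) -> np.ndarray:
    """Observed test statistic per label: pooled R (continuous) or ACC (binary)."""
    out = np.empty(result.labels.n_labels)
    for j, (nm, kind) in enumerate(zip(result.labels.names, result.labels.kinds)):
        out[j] = (result.metrics[nm]["ACC"] if kind == "binary"
                  else result.metrics[nm]["R"])
    return out


@dataclass
class PermutationResult:
    """Null distributions, p-values and the significant-edge mask.

    ``p_accuracy[j]`` tests label j's cross-validated accuracy statistic;
    ``p_weight[i, j]`` tests edge i's fold-averaged coefficient for label j;
    ``sig_mask = p_weight < alpha`` (strict).  All p-values lie in
    ``(0, 1]`` with minimum ``1 / (n_perm + 1)``.
    """

    n_perm: int
    label_names: list
    observed_stat: np.ndarray
    null_stat: np.ndarray           # n_perm x M
    p_accuracy: np.ndarray          # M
    B_bar: np.ndarray | None        # n_edges x M
    null_absB_exceed_counts: np.ndarray | None  # n_edges x M ints
    p_weight: np.ndarray | None     # n_edges x M
    alpha: float
    sig_mask: np.ndarray | None     # n_edges x M bool
    seed: int

    def summary(self) -> str:
        lines = ["Permutation test of cross-validated estimation",
                 "=" * 52,
                 f"permutations: {self.n_perm}   alpha: {self.alpha}   "
                 f"min attainable p: {1 / (self.n_perm + 1):.2g}",
                 "-" * 52,
                 f"{'label':<16}{'observed':>10}{'max null':>10}{'p':>10}"
                 f"{'sig edges':>11}"]
        for j, nm in enumerate(self.label_names):
            nsig = int(self.sig_mask[:, j].sum()) if self.sig_mask is not None else 0
            lines.append(f"{nm:<16}{self.observed_stat[j]:>10.4f}"
                         f"{self.null_stat[:, j].max():>10.4f}"
                         f"{self.p_accuracy[j]:>10.4f}{nsig:>11d}")
        return "\n".join(lines)


def run_permutation_test(features: FeatureMatrix, labels: LabelTable,
                         folds: FoldPlan, d: int = DEFAULT_D,
                         n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                         alpha: float = DEFAULT_ALPHA, label_subset=None,
                         joint: bool = True,
                         compute_weights: bool = True) -> PermutationResult:
    """Full permutation run against a frozen fold plan.

    The observed CV run and every permuted rerun use the identical
    ``folds``, so the null reflects label-feature decoupling only.  With
    ``compute_weights`` the fold-averaged coefficient matrix ``B_bar`` and
    per-edge weight p-values are accumulated as well (one extra matrix per
    permutation, no extra model fits).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if perm_pvalue(0, n_perm) > alpha:
        warnings.warn(f"n_perm={n_perm} cannot reach alpha={alpha}: "
                      f"minimum p is {perm_pvalue(0, n_perm):.3g}", stacklevel=2)
    if label_subset is not None:
        labels = labels.subset(label_subset)
    splits = [(folds.train_indices(f), folds.test_indices(f))
              for f in range(folds.k)]
    observed = run_cv(features, labels, folds, d=d, keep_models=True,
                      _splits=splits)
    obs_stat = _primary_stat(observed)
    B_bar = average_B(observed.fold_models) if compute_weights else None
    absB = np.abs(B_bar) if compute_weights else None

    M = labels.n_labels
    null_stat = np.empty((n_perm, M))
    exceed = (np.zeros_like(B_bar, dtype=np.int64) if compute_weights else None)
    rng = np.random.default_rng(seed)
    n = labels.n_subjects
    for b in range(n_perm):
        if joint:
            vals = labels.values[rng.permutation(n)]
        else:
            vals = np.column_stack([labels.values[rng.permutation(n), j]
                                    for j in range(M)])
        perm_labels = LabelTable(values=vals, names=list(labels.names),
                                 kinds=list(labels.kinds),
                                 subject_ids=list(labels.subject_ids))
        res = run_cv(features, perm_labels, folds, d=d,
                     keep_models=compute_weights, _splits=splits)
        null_stat[b] = _primary_stat(res)
        if compute_weights:
            exceed += np.abs(average_B(res.fold_models)) > absB

    stronger = (null_stat > obs_stat[None, :]).sum(axis=0)
    p_acc = np.array([perm_pvalue(int(s), n_perm) for s in stronger])
    if compute_weights:
        p_weight = (1 + exceed) / (1 + n_perm)
        sig_mask = p_weight < alpha
    else:
        p_weight = sig_mask = None
    return PermutationResult(n_perm=n_perm, label_names=list(labels.names),
                             observed_stat=obs_stat, null_stat=null_stat,
                             p_accuracy=p_acc, B_bar=B_bar,
                             null_absB_exceed_counts=exceed, p_weight=p_weight,
                             alpha=alpha, sig_mask=sig_mask, seed=seed)


def overlap_significant(mask_a, mask_b):
    """Overlap of two significant-edge sets plus hypergeometric enrichment.

    Returns ``(n_a, n_b, n_common, jaccard, enrichment_p)`` where
    ``enrichment_p`` is the probability of drawing at least ``n_common`` of
    mask_b's edges when ``n_a`` edges are drawn uniformly without replacement
    from the full edge universe.
    """
    mask_a = np.asarray(mask_a, dtype=bool).ravel()
    mask_b = np.asarray(mask_b, dtype=bool).ravel()
    if mask_a.size != mask_b.size:
        raise ValueError("masks must share the edge universe (equal lengths)")
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    n_common = int((mask_a & mask_b).sum())
    union = int((mask_a | mask_b).sum())
    jaccard = n_common / union if union else 1.0
    enrichment_p = float(hypergeom.sf(n_common - 1, mask_a.size, n_b, n_a))
    return n_a, n_b, n_common, jaccard, enrichment_p
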