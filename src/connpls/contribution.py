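"""Biological-significance diagnostics for the significant-edge sets.

Three complementary views of which connections drive the estimations:

* direct edge-label correlations — every edge feature is correlated with the
  label across subjects and ranked by |r|, so the model-derived significant
  edges can be checked for enrichment among the strongest direct correlates;
* a network partition of the ROIs by affinity propagation on a similarity
  between their connectivity profiles (the pipeline default clusters into 10
  networks; affinity propagation controls cluster count only indirectly, so
  the shared preference value is tuned by bisection until the requested
  number of exemplars emerges);
* contribution summaries — per-ROI counts of incident significant edges,
  per-network totals, and the k x k matrix of significant-edge counts
  between (and within) network pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AffinityPropagation

from .connectivity import EdgeIndexMap, FeatureMatrix

__all__ = ["NetworkPartition", "ContributionSummary", "direct_edge_correlations",
           "significant_among_top", "ap_cluster", "summarize_contribution",
           "roi_profile_similarity", "DEFAULT_TARGET_K"]

DEFAULT_TARGET_K = 10


@dataclass
class NetworkPartition:
    """ROI -> network assignment with per-network exemplar ROIs."""

    assignment: np.ndarray
    exemplars: np.ndarray
    preference_used: float
    damping: float

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.exemplars = np.asarray(self.exemplars, dtype=int)
        k = self.k
        if set(np.unique(self.assignment)) != set(range(k)):
            raise ValueError("network ids must be contiguous from 0")
        for net, ex in enumerate(self.exemplars):
            if self.assignment[ex] != net:
                raise ValueError(f"exemplar {ex} not assigned to its network {net}")

    @property
    def p(self) -> int:
        return self.assignment.size

    @property
    def k(self) -> int:
        return self.exemplars.size

    def members(self, net: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == net)


@dataclass
class ContributionSummary:
    """Significant-edge counts aggregated at ROI, network and pair level."""

    per_roi_counts: np.ndarray
    per_network_totals: np.ndarray
    network_pair_counts: np.ndarray

    @property
    def n_significant_edges(self) -> int:
        m = self.network_pair_counts
        return int(np.triu(m).sum())


def direct_edge_correlations(features: FeatureMatrix, label):
    """Pearson r of every edge with the label, plus a descending-|r| ranking.

    Returns ``(r, order)`` where ``order[0]`` is the edge index with the
    largest |r| (rank 1); ties are broken by edge index, so the ranking is
    deterministic.
    """
    label = np.asarray(label, float).ravel()
    X = features.values
    if label.size != X.shape[0]:
        raise ValueError("label length does not match subject count")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if label.std() == 0:
        raise ValueError("zero-variance label")
    xc = X - X.mean(axis=0)
    yc = label - label.mean()
    xsd = xc.std(axis=0)
    r = np.zeros(X.shape[1])
    ok = xsd > 0
    r[ok] = (xc[:, ok].T @ yc) / (X.shape[0] * xsd[ok] * yc.std())
    order = np.lexsort((np.arange(r.size), -np.abs(r)))
    return r, order


def significant_among_top(sig_mask, order, cutoffs):
    """Percentage of the top-ranked edges that are significant, per cutoff.

    ``order`` is the ranking from :func:`direct_edge_correlations`
    (``order[:c]`` are the c strongest direct correlates); the returned value
    at cutoff c is ``100 * |significant  (intersect)  top-c| / c``.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool).ravel()
    order = np.asarray(order, dtype=int).ravel()
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    if any(c < 1 or c > sig_mask.size for c in cutoffs):
        raise ValueError("cutoffs must lie in [1, n_edges]")
    return {int(c): 100.0 * float(sig_mask[order[:c]].sum()) / c for c in cutoffs}


def roi_profile_similarity(features: FeatureMatrix) -> np.ndarray:
    """Similarity between ROIs: Pearson correlation of their group-mean
    connectivity profiles (rows of the mean netmat, self-pairs excluded)."""
    emap = features.edge_map
    p = emap.p
    mean_net = np.eye(p)
    iu = np.triu_indices(p, k=1)
    mean_vec = features.values.mean(axis=0)
    mean_net[iu] = mean_vec
    mean_net.T[iu] = mean_vec
    sim = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            keep = np.ones(p, dtype=bool)
            keep[[i, j]] = False  # drop the self- and cross-entries
            a, b = mean_net[i, keep], mean_net[j, keep]
            sim[i, j] = sim[j, i] = np.corrcoef(a, b)[0, 1]
    np.fill_diagonal(sim, 0.0)
    return sim


def _ap_once(similarity, preference, damping, max_iter, convergence_iter, seed):
    ap = AffinityPropagation(affinity="precomputed", preference=preference,
                             damping=damping, max_iter=max_iter,
                             convergence_iter=convergence_iter,
                             random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap.fit(similarity)
    if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0:
        return None
    if ap.n_iter_ >= max_iter:  # did not converge
        return None
    return ap.labels_.copy(), ap.cluster_centers_indices_.copy()


def ap_cluster(similarity, target_k: int = DEFAULT_TARGET_K,
               damping: float = 0.9, max_iter: int = 1000,
               convergence_iter: int = 50, seed: int = 0,
               n_bisect: int = 40) -> NetworkPartition:
    """Affinity-propagation partition tuned to ``target_k`` clusters.

    Affinity propagation fixes the cluster count only through the shared
    preference (self-similarity) value: low preferences yield few exemplars,
    high preferences many.  The preference is tuned by bisection between the
    minimum off-diagonal similarity (and below, if needed) and the maximum
    until exactly ``target_k`` exemplars emerge; if no trial preference hits
    the target the closest achieved partition is returned with a warning.
    """
    S = np.asarray(similarity, dtype=float)
    p = S.shape[0]
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if np.max(np.abs(S - S.T)) > 1e-10:
        raise ValueError("similarity must be symmetric")
    if not 2 <= target_k <= p:
        raise ValueError(f"need 2 <= target_k <= p, got {target_k}")

    off = S[~np.eye(p, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    span = max(hi - lo, 1e-6)
    lo -= 2 * span  # ensure the low end yields few clusters
    hi += 1e-6 * span

    best = None  # (|k - target|, labels, exemplars, pref)
    def record(res, pref):
        nonlocal best
        if res is None:
            return None
        labels, ex = res
        gap = abs(len(ex) - target_k)
        if best is None or gap < best[0]:
            best = (gap, labels, ex, pref)
        return len(ex)

    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        k_mid = record(_ap_once(S, mid, damping, max_iter, convergence_iter, seed),
                       mid)
        if k_mid is None:  # non-convergence: nudge the bracket and continue
            lo = lo + 0.25 * (mid - lo)
            continue
        if k_mid == target_k:
            break
        if k_mid < target_k:
            lo = mid
        else:
            hi = mid

    if best is None:
        raise RuntimeError("affinity propagation failed to converge for every "
                           "trial preference; try a higher damping")
    gap, labels, exemplars, pref = best
    if gap != 0:
        warnings.warn(f"could not reach exactly {target_k} clusters; "
                      f"closest achieved is {len(exemplars)}", stacklevel=2)
    # relabel networks contiguously in exemplar order
    order = np.argsort(exemplars)
    exemplars = exemplars[order]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    return NetworkPartition(assignment=labels, exemplars=exemplars,
                            preference_used=float(pref), damping=damping)


def summarize_contribution(sig_mask, edge_map: EdgeIndexMap,
                           partition: NetworkPartition) -> ContributionSummary:
    """Count significant edges per ROI, per network and per network pair.

    A significant edge increments both endpoint ROIs, so the per-ROI counts
    sum to twice the number of significant edges; pair entry (a, b) counts
    significant edges with one endpoint in network a and the other in b
    (the diagonal holds within-network edges).
    """
    sig_mask = np.asarray(sig_mask, dtype=bool).ravel()
    if sig_mask.size != edge_map.n_edges:
        raise ValueError("mask length does not match the edge map")
    if edge_map.p != partition.p:
        raise ValueError("edge map and partition disagree on ROI count")
    pairs = edge_map.pairs[sig_mask]
    per_roi = np.bincount(pairs.ravel(), minlength=edge_map.p)
    k = partition.k
    per_net = np.array([per_roi[partition.members(g)].sum() for g in range(k)])
    pair_counts = np.zeros((k, k), dtype=int)
    for i, j in pairs:
        a, b = partition.assignment[i], partition.assignment[j]
        pair_counts[a, b] += 1
        if a != b:
            pair_counts[b, a] += 1
    return ContributionSummary(per_roi_counts=per_roi,
                               per_network_totals=per_net,
                               network_pair_counts=pair_counts)
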