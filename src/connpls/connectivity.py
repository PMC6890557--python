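"""Connectivity matrices (netmats) from ROI time-series and their edge vectorization.

Two connectivity definitions are supported: full (Pearson) correlation and
ridge-regularized partial correlation.  Full correlation between two regions
reflects both direct and indirect coupling; partial correlation conditions on
all other regions and is therefore a better approximation to direct
connections.  The partial correlation is computed from a ridge-regularized
precision matrix: with ``S`` the sample covariance of the (column-demeaned)
time-series,

    Theta = inv(S + rho * (trace(S) / p) * I)
    r_ij  = -Theta_ij / sqrt(Theta_ii * Theta_jj)   (i != j)

The ridge level ``rho`` multiplies the mean diagonal of ``S`` so that it is
unit-free (the FSLNets convention).  ``rho = 0.01`` is the default used
throughout the pipeline.

Edge features are the strict upper triangle of the netmat, flattened in
lexicographic (row-major) order of ROI pairs ``(i, j)`` with ``i < j``; for
``p`` regions this yields ``p * (p - 1) / 2`` edges (19,900 for ``p = 200``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "EdgeIndexMap",
    "FeatureMatrix",
    "full_correlation",
    "partial_correlation",
    "vectorize_upper",
    "build_feature_matrix",
]

DEFAULT_RHO = 0.01


@dataclass(frozen=True)
class EdgeIndexMap:
    """Fixed ordering of ROI pairs defining the edge-feature dimension.

    Edges are the pairs ``(i, j)`` with ``0 <= i < j < p``, ordered
    lexicographically; edge ``k`` of this map is feature column ``k`` of every
    :class:`FeatureMatrix` built with it.
    """

    p: int

    @property
    def n_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def pairs(self) -> np.ndarray:
        """(n_edges, 2) integer array of ROI pairs, lexicographic order."""
        iu = np.triu_indices(self.p, k=1)
        return np.column_stack(iu)

    def edge_index(self, i: int, j: int) -> int:
        """Flat edge index of the pair ``(i, j)`` (order-insensitive)."""
        if i == j:
            raise ValueError("self-pairs are not edges")
        i, j = (i, j) if i < j else (j, i)
        if not (0 <= i < j < self.p):
            raise ValueError(f"pair ({i}, {j}) out of range for p={self.p}")
        # edges before row i: sum_{r<i} (p-1-r); offset within row: j - i - 1
        return i * (2 * self.p - i - 1) // 2 + (j - i - 1)

    def edge_names(self) -> list[str]:
        return [f"roi{i}__roi{j}" for i, j in self.pairs]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A single subject's p x p network matrix."""

    values: np.ndarray
    method: str  # "full" | "partial"
    rho: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureMatrix:
    """Subjects x edges feature table with an explicit edge-index map."""

    values: np.ndarray
    edge_map: EdgeIndexMap
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (subjects x edges)")
        if self.values.shape[1] != self.edge_map.n_edges:
            raise ValueError(
                f"feature column count {self.values.shape[1]} does not match "
                f"edge map ({self.edge_map.n_edges} edges for p={self.edge_map.p})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.edge_map.edge_names(),
        )


def _validated_ts(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time-series must be 2-D (timepoints x ROIs)")
    T, p = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 timepoints, got {T}")
    dead = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if dead.size:
        raise ValueError(f"constant time-series for ROI(s) {dead.tolist()}")
    return ts


def full_correlation(ts: np.ndarray) -> ConnectivityMatrix:
    """Full (Pearson) correlation netmat of a timepoints x ROIs series."""
    ts = _validated_ts(ts)
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(values=r, method="full")


def partial_correlation(ts: np.ndarray, rho: float = DEFAULT_RHO) -> ConnectivityMatrix:
    """Ridge-regularized partial-correlation netmat.

    Parameters
    ----------
    ts : array, shape (T, p)
        ROI time-series.
    rho : float
        Unit-free ridge level; the regularizer added to the covariance is
        ``rho * mean(diag(S)) * I``.  ``rho = 0`` gives the unregularized
        partial correlation and requires the covariance to be invertible.
    """
    ts = _validated_ts(ts)
    if rho < 0:
        raise ValueError("rho must be >= 0")
    T, p = ts.shape
    x = ts - ts.mean(axis=0)
    S = x.T @ x / (T - 1)
    reg = S + rho * (np.trace(S) / p) * np.eye(p)
    try:
        theta = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; use rho > 0 "
            "(unavoidable at rho = 0 when timepoints <= ROIs)"
        ) from exc
    d = np.sqrt(np.diag(theta))
    r = -theta / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(values=r, method="partial", rho=rho)


def vectorize_upper(cm: ConnectivityMatrix | np.ndarray) -> tuple[np.ndarray, EdgeIndexMap]:
    """Flatten the strict upper triangle of a symmetric netmat into edge features."""
    values = cm.values if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(values - values.T)) > 1e-10:
        raise ValueError("matrix is asymmetric beyond tolerance 1e-10")
    p = values.shape[0]
    emap = EdgeIndexMap(p)
    vec = values[np.triu_indices(p, k=1)]
    return vec, emap


def connectivity_of(ts: np.ndarray, method: str = "partial",
                    rho: float = DEFAULT_RHO) -> ConnectivityMatrix:
    if method == "full":
        return full_correlation(ts)
    if method == "partial":
        return partial_correlation(ts, rho=rho)
    raise ValueError(f"unknown connectivity method {method!r}")


def build_feature_matrix(timeseries, method: str = "partial", rho: float = DEFAULT_RHO,
                         subject_ids=None) -> FeatureMatrix:
    """Edge-feature matrix from a sequence of per-subject time-series.

    Row ``s`` is ``vectorize_upper`` of subject ``s``'s netmat; subject order
    is preserved.
    """
    timeseries = list(timeseries)
    if not timeseries:
        raise ValueError("no subjects given")
    shapes = {np.asarray(ts).shape[1] for ts in timeseries}
    if len(shapes) != 1:
        offenders = [s for s, ts in enumerate(timeseries)
                     if np.asarray(ts).shape[1] != np.asarray(timeseries[0]).shape[1]]
        raise ValueError(f"inconsistent ROI counts across subjects: {sorted(shapes)} "
                         f"(offending subjects {offenders})")
    rows = []
    emap = None
    for ts in timeseries:
        vec, emap = vectorize_upper(connectivity_of(ts, method=method, rho=rho))
        rows.append(vec)
    return FeatureMatrix(values=np.vstack(rows), edge_map=emap,
                         subject_ids=list(subject_ids) if subject_ids is not None else [])
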