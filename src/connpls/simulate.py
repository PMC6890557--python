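"""Synthetic resting-state datasets with controllable connectivity-label coupling.

The generator emulates the statistical structure the estimation pipeline
assumes, so that every downstream stage (connectivity, PLS, cross-validation,
permutation inference, contribution analysis) is testable end-to-end without
any external data:

* ROI time-series are mixtures of shared network latent signals plus
  ROI-unique noise; regions are assigned round-robin to ``n_networks``
  communities.
* A sparse set of "effect" edges per label carries direct pairwise coupling:
  each effect edge ``(i, j)`` has its own latent signal fed into both
  endpoint ROIs with a per-subject amplitude, so the strength of that direct
  connection varies across subjects.
* Each continuous label is a weighted sum of the subject's effect-edge
  coupling strengths, scaled by ``effect_size``, plus unit-variance Gaussian
  noise; ``effect_size = 0`` decouples labels from the brain entirely (the
  calibration condition) and ``effect_size = inf`` makes labels noise-free
  deterministic functions of the connectivity strengths.
* A binary label is obtained by thresholding its latent continuous variable
  at the sample median, giving balanced classes.
* ``inter_label_corr`` routes part of the noise through a factor shared by
  all labels of a subject; family members (optional) share an additive
  random intercept on the label latents.
* A per-subject jitter on the global network-coupling amplitude makes full
  correlations noisier than partial correlations on non-effect edges,
  emulating the advantage of conditioning out indirect paths.

All randomness derives from one master seed through independent named
streams, so adding a new draw does not perturb earlier ones and the same
``(config, seed)`` reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EdgeIndexMap

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset",
           "ground_truth_mask", "write_dataset"]

# named substreams of the master seed
_STREAM_STRUCTURE = 0
_STREAM_STRENGTHS = 1
_STREAM_TIMESERIES = 2
_STREAM_LABELS = 3
_STREAM_FAMILY = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(stream,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults give a small, moderately coupled cohort: 200 subjects, 15
    regions in 3 networks, 200 timepoints, 8 effect edges per label,
    three continuous labels plus one binary, moderate signal
    (``effect_size = 2``, i.e. signal sd twice the noise sd) and mild
    inter-label correlation.
    """

    n_subjects: int = 200
    n_rois: int = 15
    n_timepoints: int = 200
    n_networks: int = 3
    n_effect_edges: int = 8
    effect_size: float = 2.0
    label_spec: tuple = (("score_a", "continuous"), ("score_b", "continuous"),
                         ("score_c", "continuous"), ("group", "binary"))
    inter_label_corr: float = 0.3
    strength_range: tuple = (0.2, 1.5)
    family_sizes: tuple | None = None
    family_effect_sd: float = 0.0
    network_coupling: float = 0.6
    subject_coupling_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_rois", "n_timepoints", "n_networks",
                     "n_effect_edges"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        p = self.n_rois
        if self.n_effect_edges > p * (p - 1) // 2:
            raise ValueError("n_effect_edges exceeds the number of edges p(p-1)/2")
        if self.n_networks > p:
            raise ValueError("n_networks cannot exceed n_rois")
        if not 0.0 <= self.inter_label_corr <= 1.0:
            raise ValueError("inter_label_corr must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.strength_range
        if not (0 < lo < hi):
            raise ValueError("strength_range must satisfy 0 < low < high")
        object.__setattr__(self, "strength_range", (float(lo), float(hi)))
        if self.family_sizes is not None:
            object.__setattr__(self, "family_sizes", tuple(self.family_sizes))
            if sum(self.family_sizes) != self.n_subjects:
                raise ValueError("family_sizes must sum to n_subjects")
            if any(s <= 0 for s in self.family_sizes):
                raise ValueError("family sizes must be positive")
        kinds = {k for _, k in self.label_spec}
        if not kinds <= {"continuous", "binary"}:
            raise ValueError(f"unknown label kind(s) {kinds - {'continuous', 'binary'}}")


@dataclass
class SyntheticDataset:
    """A simulated cohort with known ground truth.

    ``timeseries`` holds one (T x p) array per subject; ``labels`` is the
    n x M label matrix in ``label_names`` order; ``true_effect_edges[m]`` and
    ``true_coefficients[m]`` give label m's generating edges (flat indices
    into the lexicographic upper-triangle edge order) and weights;
    ``edge_strengths`` holds the per-subject coupling amplitudes on the union
    of effect edges (columns in ``strength_edge_index`` order).
    """

    config: SimulationConfig
    timeseries: list
    labels: np.ndarray
    label_names: list
    label_kinds: list
    true_effect_edges: list
    true_coefficients: list
    family_id: np.ndarray
    edge_strengths: np.ndarray
    strength_edge_index: np.ndarray
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(len(self.timeseries))]

    @property
    def n_subjects(self) -> int:
        return len(self.timeseries)

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def edge_map(self) -> EdgeIndexMap:
        return EdgeIndexMap(self.config.n_rois)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels,
                            index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.label_names)


def ground_truth_mask(dataset: SyntheticDataset, label_index: int) -> np.ndarray:
    """Boolean vector over all edges, true at ``label_index``'s effect edges."""
    if not 0 <= label_index < dataset.n_labels:
        raise IndexError(f"label_index {label_index} out of range "
                         f"for {dataset.n_labels} labels")
    mask = np.zeros(dataset.edge_map.n_edges, dtype=bool)
    mask[np.asarray(dataset.true_effect_edges[label_index], dtype=int)] = True
    return mask


def _family_ids(config: SimulationConfig) -> np.ndarray:
    if config.family_sizes is None:
        return np.arange(config.n_subjects)
    return np.repeat(np.arange(len(config.family_sizes)), config.family_sizes)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one cohort under ``config``; pure function of (config, seed)."""
    p = config.n_rois
    n = config.n_subjects
    T = config.n_timepoints
    k = config.n_networks
    emap = EdgeIndexMap(p)
    M = len(config.label_spec)

    # --- fixed structure -------------------------------------------------
    rng_s = _rng(config.seed, _STREAM_STRUCTURE)
    network_of = np.arange(p) % k  # round-robin ROI -> network
    effect_edges, coefficients = [], []
    for _ in range(M):
        edges = np.sort(rng_s.choice(emap.n_edges, size=config.n_effect_edges,
                                     replace=False))
        coefs = rng_s.uniform(0.5, 1.5, size=config.n_effect_edges)
        coefs *= rng_s.choice([-1.0, 1.0], size=config.n_effect_edges)
        effect_edges.append(edges)
        coefficients.append(coefs)
    union_edges = np.unique(np.concatenate(effect_edges))
    pairs = emap.pairs[union_edges]  # (n_union, 2) ROI endpoints

    # --- per-subject coupling strengths ---------------------------------
    rng_a = _rng(config.seed, _STREAM_STRENGTHS)
    lo, hi = config.strength_range
    amplitudes = rng_a.uniform(lo, hi, size=(n, union_edges.size))
    coupling = config.network_coupling + config.subject_coupling_sd * rng_a.standard_normal(n)
    coupling = np.clip(coupling, 0.05, None)

    # population covariance of each subject's time-series is known in closed
    # form; the label-generating "strength" of an effect edge is the
    # subject's population partial correlation on it, so labels are linear
    # in exactly the quantity the (partial-correlation) features estimate
    strengths = np.empty_like(amplitudes)
    same_net = network_of[:, None] == network_of[None, :]
    for s in range(n):
        Sigma = np.where(same_net, coupling[s] ** 2, 0.0)
        for e, (i, j) in enumerate(pairs):
            Sigma[i, j] += amplitudes[s, e]
            Sigma[j, i] += amplitudes[s, e]
        Sigma[np.diag_indices(p)] = coupling[s] ** 2 + 1.0
        for e, (i, j) in enumerate(pairs):
            Sigma[i, i] += amplitudes[s, e]
            Sigma[j, j] += amplitudes[s, e]
        theta = np.linalg.inv(Sigma)
        dd = np.sqrt(np.diag(theta))
        for e, (i, j) in enumerate(pairs):
            strengths[s, e] = -theta[i, j] / (dd[i] * dd[j])

    # --- time-series -----------------------------------------------------
    rng_t = _rng(config.seed, _STREAM_TIMESERIES)
    timeseries = []
    for s in range(n):
        z = rng_t.standard_normal((T, k))           # network latents
        u = rng_t.standard_normal((T, union_edges.size))  # edge latents
        eps = rng_t.standard_normal((T, p))
        x = coupling[s] * z[:, network_of] + eps
        amp = np.sqrt(amplitudes[s])                # coupling amplitude per edge
        for e, (i, j) in enumerate(pairs):
            x[:, i] += amp[e] * u[:, e]
            x[:, j] += amp[e] * u[:, e]
        timeseries.append(x)

    # --- labels ----------------------------------------------------------
    rng_y = _rng(config.seed, _STREAM_LABELS)
    rng_f = _rng(config.seed, _STREAM_FAMILY)
    family_id = _family_ids(config)
    fam_intercept = np.zeros(n)
    if config.family_effect_sd > 0:
        per_family = config.family_effect_sd * rng_f.standard_normal(family_id.max() + 1)
        fam_intercept = per_family[family_id]
    shared = rng_y.standard_normal(n)  # subject factor shared by all labels
    ilc = config.inter_label_corr

    col_of = {e: idx for idx, e in enumerate(union_edges)}
    labels = np.empty((n, M))
    kinds, names = [], []
    for m, (name, kind) in enumerate(config.label_spec):
        cols = [col_of[e] for e in effect_edges[m]]
        signal = strengths[:, cols] @ coefficients[m]
        sd = signal.std()
        signal = (signal - signal.mean()) / sd if sd > 0 else signal * 0.0
        noise = (np.sqrt(ilc) * shared
                 + np.sqrt(1.0 - ilc) * rng_y.standard_normal(n))
        if np.isinf(config.effect_size):
            latent = signal
        else:
            latent = config.effect_size * signal + noise
        latent = latent + fam_intercept
        if kind == "binary":
            labels[:, m] = (latent >= np.median(latent)).astype(float)
        else:
            labels[:, m] = latent
        kinds.append(kind)
        names.append(name)

    return SyntheticDataset(config=config, timeseries=timeseries, labels=labels,
                            label_names=names, label_kinds=kinds,
                            true_effect_edges=effect_edges,
                            true_coefficients=coefficients,
                            family_id=family_id, edge_strengths=strengths,
                            strength_edge_index=union_edges)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write the cohort as plain-text files; returns the paths written.

    Layout: one headerless TSV time-series per subject (T rows x p columns),
    a manifest TSV (subject_id, file, family_id), a labels TSV (subject_id +
    one column per label) and a ground-truth JSON (effect edges, generating
    coefficients, config echo).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    rows = []
    for sid, fam, ts in zip(dataset.subject_ids, dataset.family_id,
                            dataset.timeseries):
        fname = f"{sid}.tsv"
        np.savetxt(ts_dir / fname, ts, delimiter="\t", fmt="%.17g")
        rows.append({"subject_id": sid, "file": f"timeseries/{fname}",
                     "family_id": int(fam)})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    labels_path = outdir / "labels.tsv"
    dataset.labels_frame().to_csv(labels_path, sep="\t",
                                  float_format="%.17g")
    truth_path = outdir / "ground_truth.json"
    cfg = asdict(dataset.config)
    cfg["label_spec"] = [list(x) for x in cfg["label_spec"]]
    if cfg["family_sizes"] is not None:
        cfg["family_sizes"] = list(cfg["family_sizes"])
    cfg["effect_size"] = (None if np.isinf(dataset.config.effect_size)
                          else dataset.config.effect_size)
    truth = {
        "config": cfg,
        "label_names": dataset.label_names,
        "label_kinds": dataset.label_kinds,
        "true_effect_edges": [e.tolist() for e in dataset.true_effect_edges],
        "true_coefficients": [c.tolist() for c in dataset.true_coefficients],
        "edge_order": "lexicographic upper triangle, 0-based (i<j)",
    }
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"manifest": manifest, "labels": labels_path, "ground_truth": truth_path,
            "timeseries_dir": ts_dir}
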