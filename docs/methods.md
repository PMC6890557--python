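# Methods

## Connectivity estimation

Per subject, the input is a `T × p` matrix of ROI time-series. Two netmat
definitions are provided:

* **Full correlation** — pairwise Pearson correlation; sensitive to both
  direct and indirect coupling.
* **Partial correlation** — from the ridge-regularized precision matrix
  `Θ = (S + ρ · tr(S)/p · I)⁻¹`, with `r_ij = −Θ_ij / √(Θ_ii Θ_jj)` off the
  diagonal. The ridge level `ρ` multiplies the mean diagonal of the sample
  covariance `S`, so it is unit-free (the FSLNets convention); the default
  is `ρ = 0.01`. At `ρ = 0` this is the plain inverse-covariance partial
  correlation and requires `T > p`.

Time-series are column-demeaned; covariance uses the `1/(T−1)` estimator.
No Fisher r-to-z transform is applied to netmat entries before modeling
(raw coefficients enter the feature matrix; no standardization or scaling of
features anywhere in the pipeline). Edge features are the strict upper
triangle in lexicographic `(i, j)`, `i < j`, 0-based order; this order is
echoed into every output sidecar.

## Partial least squares

The core estimator is multi-response PLSR via **SIMPLS**: weight vectors are
extracted from the successively deflated cross-covariance `X₀ᵀY₀` of the
column-centered blocks, X-scores are orthonormal, and the coefficient matrix
is `B = W Qᵀ` with `intercept = ȳ − x̄ B`. SIMPLS was chosen over NIPALS
because its deflation acts on the cross-covariance and it reproduces the
widely used MATLAB `plsregress` behavior; at `d = rank(X₀)` the fit equals
the OLS pseudoinverse solution, which the tests exploit as an oracle.

* `d` — number of latent components; the only hyper-parameter. Default 50
  (the headline configuration for cohort-scale data); hard-capped at
  `min(n−1, N)`, with a warning beyond 200 where accuracy is known to
  deteriorate. If the cross-covariance is numerically exhausted early
  (rank-deficient data), extraction stops and `d` shrinks with a warning.
* Centering only, on both blocks; binary labels enter the Y block as 0/1
  numeric columns next to continuous ones.
* Fitting is fully deterministic.

The **kernel variant** uses the dual (Gram-matrix) formulation: score pairs
are extracted from the double-centered training Gram matrix by the dual
NIPALS iteration, and prediction applies dual coefficients
`α = U (Tᵀ K U)⁻¹ TᵀY₀` to the consistently centered cross-kernel. With a
linear kernel this reproduces primal PLS predictions (exactly for one label
or at full rank — the verification route in the tests). The default kernel
is RBF with `σ = 150`, the reference bandwidth for edge-feature inputs of
cohort scale.

## Cross-validation protocol

`k`-fold (default 10) with a reusable, explicit `FoldPlan`. Per fold the
model — including feature/label means — is fitted on training rows only;
pooled out-of-fold predictions give one metric per label per experiment
(pooling chosen over per-fold averaging; at cohort sizes the difference is
negligible, and pooling matches reporting one R per label). Continuous
labels: Pearson R and RMSE (`√MSE`, no degrees-of-freedom correction).
Binary labels: estimates thresholded at 0.5 (≥ 0.5 → 1) for accuracy, plus
rank-based AUC with ties counted one half.

Grouped (family-aware) folds assign whole families greedily, descending
size onto the currently smallest fold; exact balance is not guaranteed with
large families. The same fold plan is reused across estimation sets,
sweeps and permutations so that comparisons isolate the manipulated factor.

The four **estimation sets** differ only in the labels entered: main labels
jointly, supplementary labels jointly, all labels jointly, and one
single-label run per main label.

## Permutation inference

The null hypothesis is label-feature independence. Each of `N` permutations
applies **one joint row shuffle** to the whole label matrix (preserving
inter-label correlation under the null — the structure multi-label PLS
exploits; per-label shuffling is available behind a flag) and re-runs the
identical CV pipeline against the frozen fold plan. P-values use the
add-one estimator `(1 + #exceedances)/(1 + N)` with *strict* exceedance
counting (ties are not exceedances — conservative), so p ∈ (0, 1] with
floor `1/(N+1)`; the default `N = 5000` gives 0.0002.

Per-label accuracy statistics are pooled R (continuous) or accuracy
(binary). Edge-weight significance uses the fold-averaged coefficient
matrix `B̄` and compares `|B̄ᵢⱼ|` against its permuted counterparts; the
significant mask is `p < α` (strict, default α = 0.05) with **no
multiple-testing correction** across the edges × labels grid — the mask is
a raw-threshold descriptive set, not an FWER-controlled one.

## Contribution analysis

* **Direct correlations** — per-edge Pearson r with the label, ranked by
  |r| descending, ties broken by edge index (deterministic).
* **Network partition** — affinity propagation on a ROI × ROI similarity.
  The default similarity is the Pearson correlation between the ROIs'
  group-mean connectivity profiles (rows of the mean netmat, self- and
  cross-entries excluded); message passing is delegated to
  scikit-learn's implementation (damping 0.9, max 1000 iterations,
  convergence window 50). Affinity propagation controls cluster count only
  through the shared preference value, so the preference is tuned by
  bisection until the target count (default 10) of exemplars emerges; if
  unreachable, the closest achieved partition is returned with a warning.
* **Summaries** — contribution is binary (an edge is significant or not):
  per-ROI counts of incident significant edges, per-network totals, and the
  symmetric network-pair count matrix (diagonal = within-network edges).
  The upper triangle plus diagonal of the pair matrix conserves the total
  significant-edge count.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not fMRI physics, motion, or ICA parcellation:

* ROIs are assigned round-robin to `k` networks; each subject's time-series
  mixes unit-variance network latent signals (amplitude
  `network_coupling = 0.6` jittered per subject with sd 0.25 — this
  label-irrelevant variation is what makes full correlations noisier than
  partial ones on indirect edges), ROI-unique noise, and per-edge latent
  signals on a sparse set of effect edges with per-subject amplitudes
  drawn uniformly from `strength_range = (0.2, 1.5)`.
* The population covariance of this model is known in closed form, so each
  effect edge's **connectivity strength** is defined as the subject's
  population partial correlation on it. Continuous labels are
  `effect_size × (standardized weighted sum of strengths) + noise` with
  unit-variance noise; `effect_size = 0` decouples labels entirely (the
  calibration condition), `effect_size = ∞` makes them noise-free.
  Per-label effect-edge sets (8 by default) and weights (uniform 0.5–1.5,
  random sign) are drawn once per cohort.
* `inter_label_corr` (default 0.3) routes part of the noise through a
  factor shared by all of a subject's labels. The binary label thresholds
  its latent at the sample median (balanced classes, matching near-balanced
  sex splits in reference cohorts). Families, when configured, share an
  additive random intercept on the label latents (sd `family_effect_sd`,
  default 0).
* All draws derive from one master seed through fixed named substreams
  (structure / strengths / time-series / labels / family), so adding a new
  draw in one stream cannot perturb the others, and `(config, seed)` is
  bit-reproducible.

What passing tests on these cohorts do **not** show: robustness to
scanner/motion artifacts, non-linear hemodynamic label couplings, realistic
SNR of human phenotypes (no public reference for the label SNR exists, so
defaults were chosen for testability), or spatial parcellation effects.

## Problem sizes used in the test suite

Chosen to make each statistical claim decidable while a full run stays a
desk-scale computation:

* Type-I calibration: 200 independent null cohorts (n = 150, p = 15,
  T = 150, 5 folds, d = 5, 99 permutations).
* Effect recovery & mask overlap: n = 300, p = 15, T = 400, 10 effect
  edges/label, effect_size = 6, 199 permutations.
* Noise-free pipeline check: n = 200, T = 2400 — at shorter scans the
  netmat sampling noise (∝ 1/√T), not the generative law, bounds R.
* d-sweep stability (d = 10…150): n = 600, p = 40 (780 edges), 5 folds,
  keeping d well below the training size of 480, as in the cohort-scale
  setting the sweep mirrors; at much smaller n the upper end of the sweep
  overfits and the stability property genuinely disappears.

## Numerical choices and degenerate inputs

* Singular values below `1e−12` of the leading one terminate SIMPLS
  extraction (rank exhaustion).
* Constant ROI time-series, zero-variance labels, non-{0,1} binary codings,
  missing values, asymmetric matrices (beyond 1e−10) and mismatched
  dimensions are hard errors naming the offender.
* `partial_correlation` with `ρ = 0` and `T ≤ p` raises with advice to use
  `ρ > 0`.
* Floats are written with 17 significant digits and parsed with
  round-trip precision, so text round trips are exact.

## Known limitations

* Accuracy p-values for binary labels use classification accuracy, whose
  discreteness can produce ties; strict exceedance counting keeps the test
  conservative in that case.
* The preference bisection cannot always realize an exact target cluster
  count (affinity propagation's count is a step function of the
  preference); the closest partition is returned with a warning.
* Grouped folds optimize balance greedily, not optimally.
* No multiple-testing correction is applied to edge-weight p-values by
  design; downstream users needing FWER/FDR control must apply it to the
  exported p-value tables.
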