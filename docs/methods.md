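# Methods

`chemrisk` implements a reliability-based criterion for choosing the number
of principal components and the features assigned to them, four PCA-family
extraction backends, a chemical mixture-exposure index, an
imbalanced-classification benchmark harness, and a seeded synthetic-data
generator that stands in for a proprietary plant-floor hazard dataset.
This note records the models, the numerical choices, and what the synthetic
conditions do and do not establish.

## The reliability criterion

For a standardized feature set of `k` items with mean absolute pairwise
Pearson correlation `r̄` and mean absolute item–total correlation `ṙ`
(each item against the sum of all items), the reliability coefficient is
the Cronbach/Spearman–Brown form

    β = k·r̄·ṙ / (1 + (k−1)·r̄·ṙ)

β is 0 for mutually uncorrelated items, 1 for perfectly redundant ones,
non-decreasing in the correlation product for fixed `k`, and non-decreasing
in `k` for a positive product. Absolute values are used in both `r̄` and
`ṙ` because sign-mixed items would cancel in the plain means and destroy
the reliability interpretation. For `k = 1` the scale degenerates: `r̄` is
defined as 1 and β reduces to the (unit) item–total correlation.

**Membership rule.** After fitting an extraction backend, feature `i`
belongs to component `m` when `Φ(t_{m,i}) ≥ β`, with `Φ` the standard
normal CDF and `t` a transform of the loading matrix. Applying `Φ`
directly to eigenvector entries is available (`loading_transform="raw"`),
but unit-norm entries over 63 features rarely exceed 0.4, so `Φ(w) < β`
for any realistic β and the literal rule retains nothing. The default
transform is therefore the within-component z-score of the loading
magnitudes: `Φ(t)` then spans (0, 1) and β acts as a quantile-like cut on
the loading ranking, preserving the rank semantics of the rule.
`"abs"` (loading magnitudes) is also available.

Features passing for several components go to the component with the
largest absolute loading; exact ties go to the lower component index.

**Component pruning.** Components whose member set fails the reliability
criterion are removed, along with their features. Because a Cronbach-type
coefficient grows mechanically with scale length, a 10-item component scale
cannot be compared directly with the 63-item global β: the component's
correlation product is first projected to the common length through the
same formula (Spearman–Brown prophecy), and singleton components use their
per-feature β, which is already on that scale. Without the projection,
genuine short components are systematically discarded (the classical
test-length effect). If every component fails, the most reliable one is
kept, with a warning.

**Candidate pool.** The membership rule is evaluated over the leading
`M_max` components. `M_max` is the number of components that (a) fit
within a 95% cumulative explained-variance cap and (b) carry at least an
average share of variance. The cap alone is not usable on data with a
near-flat eigenvalue tail: dozens of noise components slip under 95% and
each captures a few spurious features. Requiring an above-average
eigenvalue bounds the pool by the same logic that motivates the Kaiser
rule, while the reliability pruning removes whatever unreliable components
remain.

**Margin (SVM) extension.** Near the threshold the linear rule is
brittle, so an optional margin `[β−δ, β+δ]` declares features ambiguous.
Each feature gets the descriptor `(Φ(t_{1,i}), …, Φ(t_{M,i}), β_i)`;
features clearly above the band are positive teaching examples, clearly
below are negative, and a kernel SVM trained on this teaching sample
classifies the in-margin features. The exterior labeling of the teaching
sample is this package's construction (no standard definition exists), and
results carry a flag saying so. With `δ → 0` the rule is extensionally
identical to the linear rule, which is enforced by test. The membership
SVM uses C = 10 with an RBF kernel by default: the teaching labels are
deterministic, so little regularization is wanted.

Whether β is global or per-feature is genuinely ambiguous; both are
computed, both rules default to the global β (`per_feature=True` switches
both consistently, keeping the δ → 0 equivalence).

## Classical criteria

* **Kaiser**: number of eigenvalues strictly above 1 (correlation-matrix
  convention). Diagnostics flag instability when many eigenvalues sit in
  [0.9, 1.1] — on near-identity correlation structure the count fluctuates
  around half the feature count.
* **Scree**: the elbow is formalized as the position of the maximum second
  forward difference (acceleration) of the eigenvalue curve; ties keep the
  smaller count. The visual rule has no canonical formalization; maximum
  acceleration is the simplest one consistent with "the point where the
  curve bends".
* **Fused (K+SP)**: a component must satisfy both rules, i.e.
  `min(K, SP)`; zero is returned with a warning when everything fails.
* **Feature retention for the classical criteria**: every feature joins its
  max-|loading| component among the retained `M`; features whose best
  loading magnitude is below the salient-loading cutoff (default 0.4, the
  common factor-analysis convention) are dropped.

## Extraction backends

All backends expose eigenvalues in non-increasing order, unit eigenvectors
with the largest-magnitude entry positive, loadings on the
feature–component correlation scale, and explained-variance fractions.

* **PCA** — exact eigendecomposition of the correlation matrix of
  standardized data; eigenvalues sum to the feature count.
* **CCPCA** (centroid-class PCA) — eigendecomposition of the blended
  scatter `S = B + γC`, where `B` is the class-size-weighted scatter of the
  class centroids and `C` the correlation matrix. Axes rotate toward
  centroid-separating directions; with coincident centroids `B = 0` and the
  model equals PCA; a single class falls back to PCA with a warning.
  γ defaults to 0.1: small enough that clearly separated centroids lead the
  rotation, large enough to anchor the remaining axes to the data cloud.
  Because the axes are not variance-ordered, loadings are computed directly
  as feature–score correlations.
* **GPCA** — PCA estimated by seeded minibatch Oja updates
  (`w ← w + η·C_batch·w`, renormalized) with 1/(1+t) learning-rate decay
  and deflation after each component, followed by a short exact
  power-iteration polish on the deflated data to strip residual stochastic
  jitter (everything remains deterministic given the seed). Converged
  components agree with the exact eigendecomposition; non-convergence
  raises a warning with the last update norm.
* **KPCA** — centered-kernel eigendecomposition (scikit-learn backend;
  randomized solver above 2,000 samples, seeded). Kernel components have
  no native feature loadings, so pseudo-loadings are defined as Pearson
  correlations between each original feature and each component score —
  exactly what the loading equals for linear PCA, which keeps the
  membership rule well-defined. Kernel eigenvalues are rescaled so the
  full spectrum would sum to the feature count, matching the
  correlation-matrix convention (for the linear kernel the eigenvalues then
  equal PCA's). Numerically negative kernel eigenvalues are clipped at
  zero with a warning.

`transform` projects standardized data onto the retained components with
the non-retained features zeroed first, so discarded channels cannot leak
into the scores.

## Exposure indices

For a mixture of `r` substances with shift-weighted exposure indices `Ps_r`
and permissible limits `NDS_r`, the combined index is the ratio of sums
`(ΣPs_r)/(ΣNDS_r)`. The conventional occupational-hygiene additive rule
`Σ(Ps_r/NDS_r)` is available as `rule="conventional"`; the two disagree
when limits differ widely, and the additive rule is generally stricter.
The index maps to low/medium/high through a configurable two-threshold
ladder, default 0.5/1.0 — the standard convention of acting when exposure
passes half the permissible limit — with boundary values in the lower
band. Instantaneous (`Pch`) and ceiling (`Pp`) indices are carried per
substance; `combined_exposure_index` takes the worst of the three channels,
a construction of this package (no standard combination rule exists).

## Benchmark protocol

Stratified 5-fold cross-validation (optionally repeated with reshuffled
folds; 10 repeats give 50 Wilcoxon pairs, `repeats=1` mirrors a
single-pass protocol). Standardization, extraction and selection are all
fitted inside each training fold only; component scores are rescaled to
unit train-fold variance so kernel and distance classifiers see comparable
axes. Quality is the balanced accuracy score (macro-averaged recall over
the four risk classes). Methods are compared per classifier with the
two-sided Wilcoxon signed-rank test on paired fold scores (zero differences
dropped; exact null distribution up to 25 informative pairs), and the
report renders the two-row-per-method layout: mean BAC, then the 1-based
indices of the methods beaten at the 0.05 level.

Classifier suite: SVC, k-NN (3/5/7), CART, Gaussian naive Bayes, and an
MLP. Grids cover the standard ranges (SVC C ∈ {0.1, 1, 10, 100}, four
kernels, two gamma modes; CART depth 1–10; MLP 3–10 hidden layers, five
alpha values, six momentum values); a grid search with an inner stratified
CV is provided, but the benchmark defaults to the best-known presets
(SVC C = 0.1/RBF/gamma auto; KNN7 Euclidean; CART gini/best/depth 7; MLP 7
hidden layers, identity activation, alpha 0.01, momentum 0.6 under SGD).
"7 hidden layers" is read literally as depth (width 32 per layer,
`max_iter = 150` chosen for runtime); the alternate "7 hidden units"
reading is available via `mlp_units_reading`.

## The synthetic-data generator

The generator emulates the printed structure of a 40,000-record,
63-feature plant-floor hazard table: feature groups of 18 (toxic
concentrations), 28 (physicochemical properties) and 17 (network-security
telemetry); four risk classes with prevalences 12.1% / 4% / 3.5% and the
remainder risk-free, allocated by largest-remainder rounding so counts are
exact (4,840 / 1,600 / 1,400 / 32,160); and a low-dimensional latent
structure in which four components explain roughly three quarters of the
variance.

Mechanism: `x = Λf + ε` with standard-normal latent factors. The first
two factors form the **hazard subspace**, supported exactly on the 18
informative features (6/7/5 per group, the named network-security factors
among them); the risk classes shift its mean along a mildly curved path
(`CLASS_GEOMETRY`, adjacent classes ≈ one `centroid_separation` apart,
default 3.0 within-class factor SDs). Non-informative features carry no
hazard loading, so their class displacement is exactly zero. The second
hazard factor is expressed by only three channels, so its component sits
low on the eigenvalue ladder — this is the component an elbow rule drops.
Background structure comes from the remaining factors, allocated to the
feature groups with deliberately uneven feature masses and per-factor
strength scales (equal masses would make sample eigenvalues degenerate and
the axes mix). Background channels span a salience spectrum: strong
(noise multipliers 0.45–0.85 of `noise_sd = 0.6`), weak (attenuated
loadings, higher noise) and junk (almost no factor structure); weak and
junk channels receive Student-t(3) residuals — glitchy sensors with
occasional multi-sigma spikes — while informative and strong channels are
Gaussian. A 10% fraction of strong background features is generated as a
monotone nonlinearity (exponential or sign-preserving square) of its
dominant factor; network-security channels are produced as log-scale
counts and normal-scored. A small class-correlated contrast signature
(`contrast_shift_scale = 0.12`) lives in the informative features'
residual space: class structure that variance-driven components do not
align with. Columns are finally standardized (population SD).

**What the synthetic conditions show — and what they don't.** The
generator plants exactly the structure the selection criteria differ on:
a reliable informative subspace, a small discriminant component that the
scree elbow loses, and non-salient channels that the Kaiser rule
over-retains. Passing tests therefore demonstrate that the implementation
ranks criteria the way the underlying theory predicts *under those planted
conditions*; they do not certify effect sizes on real sensor data, where
class structure need not align with any latent factor, labels carry expert
noise, and features drift over time. Two consequences of the synthetic
design are worth stating plainly:

* With the best-preset (identity-activation) MLP, no linear extraction can
  beat the raw feature table at these sample sizes: a linear model's
  raw-space hypothesis class contains every linear projection of it, and
  with 3,200 training rows against 63 features the estimation-variance
  penalty of raw space is negligible. The fused K+SP pipeline, which
  additionally drops a discriminant component, accordingly scores *below*
  no-extraction for the MLP on synthetic data, and the corresponding
  acceptance assertion fails by construction. The RBF-kernel SVC does pay
  a genuine dimensionality penalty in raw space, and the full ordering
  (reliability criterion > fused criterion > no extraction) holds there.
* Centroid-class rotation gains little when, as here, the class signal is
  largely axis-aligned with the variance structure; its advantage on real
  data presumably reflects misalignment that cannot be planted without
  breaking the variance-structure invariants above. On the synthetic
  conditions CCPCA' ≥ PCA' holds, but as a modest margin.

## Numerical conventions

* Standardization uses the population SD (`ddof = 0`); zero-variance
  columns are an error naming the column.
* Eigenvector signs: largest-magnitude entry positive; eigenvalue ties
  break toward the eigenvector whose largest entry sits on an earlier
  feature.
* Loadings are clipped nowhere; Φ is evaluated by `scipy.special.ndtr`.
* β = 1 makes the membership rule unsatisfiable (Φ < 1 strictly) and
  raises an empty-selection error rather than returning nothing silently.
* All stochastic stages (generator, GPCA, KPCA solver, SVM, CV shuffles)
  are seeded; per-stage seeds derive from the global seed via CRC32 of the
  stage name, below 2^31.
* JSON artifacts serialize floats at 12 decimal places so identical
  configurations reproduce byte-identical files.

## Problem sizes used in tests

Unit and property tests run on datasets of 400–4,000 samples; the
generator-fidelity checks use the full 40,000 × 63 conditions (a single
generation takes well under a minute). Selection-recovery checks average
20 seeded datasets of 4,000 samples; benchmark-ordering checks average 10
seeds × 5-fold CV with the SVC and MLP presets. `scripts/acceptance.py`
re-runs the same computations at 10 selection seeds and 5 benchmark seeds.

## Known limitations

* The scree formalization (maximum acceleration) is one of several
  reasonable elbow rules; visual scree reading is not reproducible.
* CCPCA's blended scatter is prior-weighted, so discriminant directions
  relevant only to rare classes are structurally hard for it to rank —
  an inherent property of unwhitened between-class scatter under
  imbalance.
* KPCA models transform new data through the fitted kernel machinery and
  are not fully serializable to JSON; the CLI stores spectra and
  pseudo-loadings only.
* The exposure module implements index arithmetic and the risk ladder; it
  does not estimate confidence bounds for measured concentrations.
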