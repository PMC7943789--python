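# Methods

This note documents the models, estimators, numerical choices and
limitations of the package. Notation: counts `N_t`, net growth rate `μ`
(day⁻¹), normalized growth rate `DIP`, fraction affected `fa`,
deviation from Bliss independence `DBI`.

## Growth metrics

A population observed at strictly increasing timepoints with positive
counts has per-interval net growth rate `μ = ln(N_t2/N_t1)/(t2−t1)`.
The *average* net growth rate of a condition is the unweighted mean of
the per-interval rates over consecutive observed timepoints — intervals
are not weighted by duration on uneven grids (0, 3, 5 days), and no
interpolation is performed across missing timepoints. Rates are
estimated per replicate and then averaged across replicates, rather
than pooling counts first, so replicate-to-replicate variance is
preserved for the downstream t-tests.

`DIP = μ_drug/μ_DMSO` presumes a growing control; conditions with
`μ_DMSO ≤ 0` are excluded with a logged warning instead of returning
signed infinities.

## Bliss combination scoring

`fa = (1 − DIP)/(1 − min DIP)` maps unbounded DIP values onto effect
fractions: the most effective treatment in the dataset anchors `fa = 1`.
`min DIP` is computed once per analysis dataset (every cell line and
treatment condition) and recorded in the run manifest; an explicit
override exists for cross-study reuse. `fa` values outside [0, 1]
(treatments growing faster than control) propagate with a warning and
are never clipped. `DBI = (fa_A + fa_B − fa_A·fa_B)/fa_AB`; a
combination with `fa_AB = 0` is flagged undefined rather than scored.
The categorical "additive" call uses `|DBI − 1| ≤ 0.05` by default —
the DBI definition carries no band, so this half-width is a reporting
choice of this package and is configurable.

## Screen hit calling

The effect of a compound condition is the difference between its
replicate growth rates (each measured from t0 to the readout timepoint)
and the mean of the pooled matched no-compound controls (same cell
line, MAPK condition, timepoint). Hits must pass both a statistical
filter — two-sample t-test at the Dunn–Šidák level
`1 − (1 − α)^(1/m)` — and an effect filter, a decrease of at least
0.5 day⁻¹ on the net-rate delta (`effect_on="normalized"` switches to
the dimensionless reading; the net-rate scale is the default because it
is the only one on which "day⁻¹" is a unit).

Two deliberate statistical choices:

* **Family definition.** `m` counts every compound × dose × cell line ×
  MAPK condition × timepoint comparison analyzed in one run; `m` is
  stored with the calls and in the manifest so the correction is
  auditable.
* **Pooled-variance t-test.** With two compound replicates, a
  separate-variance (Welch) test has ≈1 denominator degree of freedom
  and its tail approximation collapses exactly where the multiplicity
  correction operates (measured ~30× nominal at the corrected level).
  The pooled test borrows the large control pool's variance estimate
  and is exactly calibrated when well-to-well variability is shared
  across wells — which holds under the constant-CV count-noise model
  and approximately in imaging screens. `variance="welch"` restores the
  separate-variance test. Simulated null screens put the family-wise
  error at ≈0.03–0.05 for α = 0.05 (tests sharing a control pool are
  positively correlated, making Šidák slightly conservative).

The response matrix for mechanism clustering averages growth and
protein-log-intensity deltas over doses and timepoints per (readout,
cell line, MAPK condition) column. Clustering uses the correlation
distance with complete linkage; rows are pre-sorted lexicographically
by compound label so tied merges are bit-reproducible, zero-variance
rows (undefined correlation) are excluded with a warning, and the
dendrogram is exported as Newick text plus a flat leaf order.

## Single-cell statistics

Preprocessing is natural-log transform followed by per-marker z-scoring
across the pooled cell set, using the sample (n−1) standard deviation —
the two sd conventions differ negligibly at thousands of cells, but one
is fixed for reproducibility. Constant markers z-score to zeros with a
warning.

The Fano factor is computed on **raw** (non-log) intensities: the
variance-to-mean ratio is a dispersion index only on the measurement
scale, where Poisson-like noise gives 1. Mean pairwise distance is the
exact mean over all n(n−1)/2 Euclidean distances in z-scored marker
space, computed exactly up to 5000 cells and on a seeded subsample
above that (screen populations are of order a few thousand cells).

Gating fits a two-component Gaussian mixture to pooled log intensities
and places the threshold at the equal-posterior boundary between the
component means (solved by bracketed root finding). This automates what
is otherwise a manual histogram inspection; a manual threshold override
is mandatory when the fit is degenerate (components closer than 0.5
pooled sd, or no posterior crossing). On well-separated two-state
mixtures the recovered High fraction is within 0.02 of truth (tested).

Embedding: PCA (full SVD) with a fixed sign convention
(largest-magnitude loading positive per component), then Barnes–Hut
t-SNE on the first two PC score columns with learning rate 1000, 2000
iterations, perplexity 480 and early exaggeration 4 — settings sized
for pooled populations of ~6000 cells (60 cells subsampled per
condition across ~100 conditions). Perplexity is auto-reduced with a
warning when the population is smaller than 3×perplexity. t-SNE is a
delegated standard algorithm; its contract here is seed-reproducibility
and preservation of cluster structure (silhouette of true labels), not
specific coordinates.

## Regression models

PLSR is single-response PLS1 via NIPALS (for one response NIPALS and
SIMPLS coincide up to normalization). Inputs are z-scored across
conditions before fitting; the estimator centers internally so the fit
is invariant to that convention. The component count, when not given,
maximizes LOOCV Q² over 1..min(n−2, p) and is recorded on the model.
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = ‖t_a‖²q_a²`; `ΣVIP² = p` is an identity and is tested on every
model. The VIP sign is the sign of the Pearson correlation between the
raw predictor and the raw response (not the loading sign), so a
negative score reads directly as "higher marker, stronger kill".
Highlighted markers require |VIP| strictly > 1 *and* correlation
p < 0.05.

MLR is OLS with intercept; a rank-deficient design fails loudly with
the collinear columns named. The train/validation split sorts samples
by response (stable sort; ties keep input order) and assigns
train/train/validation repeatedly; trailing samples of an incomplete
triple go to training. 21 samples → 14/7, 7 → 5/2.

## Synthetic data

The generators emulate the study design the analysis assumes: counts at
0/3/5 days of MAPK-inhibitor exposure; a 276-compound library at 0.2
and 1 µM in duplicate with a shared 276-replicate control pool; two
cell lines under DMSO / vemurafenib / vemurafenib+trametinib
backgrounds; 58 planted true hits (20 at −1.0 day⁻¹, 38 at −0.6 day⁻¹)
against a 0.5 day⁻¹ truth threshold. Counts follow
`N(t) = N₀ e^{μt}` times mean-one log-normal noise, rounded to integers
and floored at 1 so downstream logs are always defined. The count-noise
CV is not reported by any upstream source; the 10% default is a typical
well-to-well CV for imaging-based counting and is stated as this
package's own choice. Baseline rates (0.5–0.65 day⁻¹, doubling times
~1–1.4 days) and MAPK rate reductions (−0.25 / −0.4 day⁻¹) are typical
of BRAF-mutant melanoma lines under these inhibitors. Single-cell
markers are log-normal mixtures with exact (largest-remainder)
subpopulation counts so truth-label fractions equal the configured
mixing fractions;
the regression dataset is low-rank-plus-noise features with a sparse
planted coefficient vector. One global seed spawns per-stage child
seeds (`numpy.random.SeedSequence`) in a fixed documented order, so any
stage is reproducible in isolation and identical configs give
bit-identical tables.

What the generators do **not** model: plate-edge and spatial artifacts
(edge wells are assumed excluded at the design level), segmentation
errors, marker cross-talk, heavy-tailed or correlated count noise,
dose–response curvature (planted effects are dose-independent), and
treatment-induced changes in subpopulation structure. Passing tests
therefore demonstrate correctness of the *computations* under the
stated stochastic model, not robustness to these real-data features.

## Problem sizes in tests and the demo

The default pipeline demo runs 48 compounds × 2 doses × 2 replicates ×
2 cell lines × 3 MAPK conditions (m = 1152 comparisons) with a
24-replicate control pool, 300 simulated cells per condition subsampled
to 60, and a 21-sample regression set — sizes chosen so a full run
completes in seconds while exercising every code path at realistic
ratios. Error-control and power properties are established on 1000 and
300 simulated 10-compound screens respectively; oracle-equivalence
checks use ≤50-row instances where brute force is exact.

## Known limitations

* The Šidák correction is exact only under independent tests; the
  shared control pool induces positive correlation, making control
  conservative rather than exact.
* The GMM gate assumes two log-normal-ish modes; skewed unimodal
  distributions may still yield a (meaningless) boundary — inspect
  `gates.json` and override where needed.
* LOOCV Q² with automatic component selection is mildly optimistic
  because selection uses the same folds; at screen-scale sample counts
  (n ≈ 8–21) nested cross-validation is too unstable to be preferable.
* DIP-based metrics are undefined for non-growing controls; such
  conditions are excluded, not imputed.
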