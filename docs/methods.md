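# Methods

This note documents the models, the estimators, the numerical choices and
the known limitations of `mcinet`. Empirical figures quoted here are the
ones the test suite and `scripts/acceptance.py` compute.

## Synthetic cohort model

The generator emulates ROI-level data after image preprocessing: per
subject, 68-region Desikan–Killiany morphometry and 90-region AAL BOLD
series at TR = 3 s, filtered into full (0.01–0.08 Hz), slow-4
(0.027–0.08 Hz) and slow-5 (0.01–0.027 Hz) bands. Default group sizes are
MCInc 55 / MCIc 30 / AD 19.

**Morphometry.** Cortical thickness is Normal(2.5, 0.25) mm, floored at
0.5 mm; volume and surface area are lognormal (median ≈ 2440 mm³ and
≈ 990 mm², log-scale SD 0.25). These marginals give realistic ranges and
guarantee positivity. Planted group effects are standardized mean shifts
per (region, measure), applied on the log scale for volume/area.

**Time series.** A latent multivariate Gaussian over a Watts–Strogatz
small-world backbone (k = 6, rewiring 0.1) with correlation 0.25 on
backbone edges; group-specific perturbations add a configurable delta to
every pair within a chosen node set, after which the matrix is repaired
to the nearest correlation matrix (eigenvalue floor 1e-3). White
measurement noise (SD 0.5) attenuates observed correlations by a factor
1/(1+0.5²) = 0.8 relative to the latent values. Band-limited series come
from zero-phase 4th-order Butterworth filtering (applied forward and
backward; the same filter on every channel leaves inter-regional
correlations intact), with 40 padding samples trimmed at each end to
absorb transients. The number of retained volumes defaults to 130 — an
assumption, since only the number of discarded stabilization scans (10)
is conventionally fixed; it is configurable.

`default_conversion_effects()` packages one planted scenario used by the
end-to-end checks: bilateral entorhinal/parahippocampal thickness loss
(0.8–1.0 SD), entorhinal and inferior-temporal volume loss, and a −0.35
weakening of latent coupling within a hippocampal–temporal–thalamic
node set. Magnitudes sit in the range conversion studies report for
medial-temporal atrophy.

**What the generator does not emulate:** spatial covariance of
morphometry across neighboring regions, hemodynamic response shape,
motion and physiological artifacts, scanner/site effects, and
age/sex covariates. Passing tests therefore demonstrate that the
pipeline recovers planted statistical structure of the stated form, not
that it reproduces accuracies attainable on any particular clinical
cohort.

## Networks and nodal metrics

The thickness-similarity kernel uses width α = 0.01; the functional
network applies Fisher's r-to-z with correlations clipped to
±(1 − 1e-7) so z stays finite, and a zero diagonal. Binarization keeps
the `round(cost·V(V−1)/2)` largest weights; ties at the cutoff break by
ascending (i, j) order, which makes edge sets nest as the cost grows.
Functional edges rank by *signed* weight by default (a strong negative
correlation is a weak edge); an absolute-value mode is available since
the convention is not universal.

Nodal degree, nodal path length and betweenness are computed on the
binary graphs (BFS distances via `scipy.sparse.csgraph`, betweenness via
networkx's Brandes implementation) and verified against a brute-force
oracle — hand-rolled BFS plus explicit enumeration of every shortest
path — on hundreds of random graphs with V ≤ 8. Unreachable pairs
contribute a distance of V to the path length, a finite penalty that
keeps the metric defined on the disconnected graphs low costs produce;
averaging over reachable pairs only is available
(`unreachable="reachable"`). Betweenness counts unordered pairs without
normalization; any other convention rescales all nodes equally and
cannot change feature rankings.

## The 1150-feature codec

Slots 1–68/69–136/137–204 hold raw thickness/volume/area in the
FreeSurfer `aparc` region order (left hemisphere 1–34, right 35–68);
205–272 and 273–340 hold thickness-network degree and path length;
341–610, 611–880 and 881–1150 hold the full-band, slow-4 and slow-5
functional blocks, each ordered NL, ND, BC over AAL regions 1–90. The
layout was reconstructed by solving all published index↔label pairs
simultaneously; every functional index is consistent with canonical AAL
numbering. Three published *structural* hemisphere suffixes conflict
with any single consistent ordering (e.g. index 39 decodes to the right
entorhinal under left-then-right ordering but is labeled ENT.L in the
source tables); the codec follows the ordering, not the printed
suffixes.

## Feature selection

### RSFS

Each iteration draws a uniform random subset of n = ⌈√p⌉ features,
scores it with a KNN criterion, and updates every used feature's
relevance by `r' = r + c_i − E{c}`, where `E{c}` is the running mean of
the criterion (including the current iteration — the alternative merely
rescales each step by (1−1/i) for features and dummies alike). A feature
is selected when a Gaussian fitted to dummy relevances puts its
relevance above the δ = 0.99 quantile.

Design choices that required measurement:

* **Criterion.** Balanced accuracy of a 5-NN (Euclidean, z-scored
  features), averaged over 3 fresh stratified 75/25 splits per iteration
  (`n_splits`). A single split on a sub-100-subject fold is quantized in
  ~5–10% steps; averaging three cut criterion noise ≈ 1.7× and sharpened
  the top-10 ranking markedly (mean |standardized effect| of the top 10
  rose from ≈ 0.5 to ≈ 0.7 on planted cohorts).
* **Iteration budget.** Defaults to ~50 expected inclusions per
  candidate column, `ceil(50·(p + pool)/n)`. Below ~20 inclusions the
  ranking is noise; far beyond, the relevance of features merely
  chance-correlated with the labels grows linearly in inclusion count
  while a bookkeeping null grows only as its square root, so very long
  budgets inflate false selections on small cohorts.
* **Dummy null.** Two modes. `"shared"` is the classical bookkeeping
  null: a separate dummy pool updated with the true subset's criterion
  value. It cannot see in-sample chance correlation and measured
  anti-conservative on pure noise (≈3× nominal at the default budget,
  ≈8× at long budgets). The default `"pooled"` mode instead appends
  label-decoupled dummy columns — each true column row-permuted once —
  to the candidate pool, so dummies compete inside the same subset draws
  and KNN evaluations; a dummy's relevance is then exchangeable with an
  irrelevant true feature's by construction, and the measured null false
  selection rate stays near nominal (≈1.4% at δ = 0.99) at either n = 60
  or n = 200 and does not drift with budget. The pool defaults to
  max(p, 200) columns so the fitted null's tail quantile is stable.
  In shared mode the pool is forced to p: dummies must be included at
  the true features' rate for the variances to match.
* **Residual calibration limit.** Even with the exchangeable null, the
  selection rule plugs sample (μ, σ) into a Gaussian tail at the 0.99
  quantile; the relevance distribution's tails are slightly heavy, so
  the realized false-selection count on ~100-feature problems is
  overdispersed with mean ≈ 1.7 rather than 1. Consumers needing strict
  FDR-style control should treat δ as approximate.

Ranking for top-K use is by selection probability with relevance as the
tie-break.

### mRMR

Greedy maximization of the set objective D(S) − R(S): mean
feature–class mutual information minus the mean pairwise
inter-feature MI over ordered distinct pairs with 1/|S|² normalization.
Self-information is excluded from R so the first pick is exactly the
maximum-MI feature. Features are discretized per training fold into
three bins at mean ± SD; MI is the plug-in estimate in bits. With these
conventions an *exact* duplicate of an informative feature ties with an
independent noise candidate (the duplicate's relevance and redundancy
cancel identically), while any imperfect copy loses to noise; the
implementation is verified against an exhaustive greedy oracle.

### SS-LR

Stability selection over the lasso `(1/n)‖Xw − y‖² + λ‖w‖₁` (labels
±1, no intercept, columns z-scored per subsample), solved by coordinate
descent (`sklearn.linear_model.lasso_path`, tolerance 1e-6) across the
published grid λ = 0.055 … 0.295, step 0.005. B = 100 stratified
half-subsamples; a feature's score is the maximum over λ of its nonzero
frequency (|w| > 1e-8), and the support threshold is 0.6. Note that at
the grid's smallest penalty the lasso is close to OLS, so null features
carry tiny nonzero coefficients in a nontrivial fraction of subsamples;
null stability scores up to ≈ 0.4 are normal and the 0.6 threshold is
what provides the separation.

## Classification protocol

Outer loop: leave-one-out. Inside each training fold, features are
z-scored and the selector fitted with a fold-specific seed; the top-k
features (default 10) feed an RBF-SVM whose C and σ are tuned by
stratified 10-fold grid search over {4⁻⁴ … 4⁴} × {4⁻⁴ … 4⁴}
(81 combinations), maximizing inner accuracy with ties resolved toward
the smallest C then smallest σ (smoother models). The positive class is
the later disease stage (MCIc against MCInc; AD against MCIc).
Comparators run the same outer protocol with fixed settings: random
forest (500 trees), 5-NN, AdaBoost (100 stumps); their decision score is
the positive-class probability minus ½. `selection_scope="global"`
(selection once on all data) exists for comparison but is leakage-prone
and not the default.

Resampling evaluation balances the *training* side only (duplication,
jittered duplication at 5% of per-feature SD, or down-sampling), reruns
the leave-one-out evaluation per iteration, and averages the metrics.
Feature rankings are computed once per fold on the un-resampled training
set and reused across iterations: re-running selection per iteration
would multiply cost by the iteration count while the question the
protocol answers — sensitivity of the *classifier* to class balance —
is unchanged.

Pooled out-of-fold decision scores define the ROC/AUC. Clopper–Pearson
intervals are exact beta quantiles; the DeLong variance uses placement
values, with the interval truncated to [0, 1] (it collapses to the point
under perfect separation); McNemar is the exact binomial test on
discordant pairs by default (fold counts are small), with the
continuity-corrected χ² variant available. A paired DeLong test is
provided for AUC-vs-AUC comparisons between selectors at a given K.

## Cost sweep and "best" cost

The sweep covers costs {0.08 … 0.44} and K = 1 … 30. "Best and most
stable" cost is operationalized as the maximum mean AUC over K, ties
broken by lower AUC variance over K, then lower cost. The acceptance
run uses the reduced sweep {0.19, 0.39} with K = 10 and an 80-subject
cohort so the whole end-to-end check fits in minutes; the methods and
defaults are identical at full scale.

## Known limitations

* RSFS selection-set calibration is approximate (see above); the
  *ranking* it produces is what the classification pipeline consumes.
* The synthetic generator's independence assumptions (regions, subjects)
  make planted effects easier to find than correlated real-world
  signals of equal magnitude; reported synthetic AUCs are not clinical
  performance estimates.
* Published headline accuracies from access-controlled cohorts are not
  reproducible from synthetic data and are not targeted; the package
  reproduces exactly the arithmetic, interval and codec claims that are
  recomputable, plus behavioral properties on planted designs.
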