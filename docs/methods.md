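# Methods

This note documents the generative model behind the synthetic cohorts, the
statistical procedures, the numerical and design choices made where the
problem was genuinely open, and what the tests do and do not establish.

## Synthetic multi-site cohorts

Real consortium ROI tables are private, so the package ships a generator
whose output has the statistical structure the evaluation machinery is
built to probe.  For subject *i* at site *s*, feature *j*:

    x_ij = o_sj + g_s · (a_j·(age_i − mean age) + b_j·male_i
                          + d_j·dx_i + m_j·med_i + ε_ij),  ε ~ N(0, 1)

* **Site effects.** Additive offsets `o_sj ~ N(0, site_offset_sd²)` per
  site and feature, and a multiplicative site scale
  `g_s = exp(N(0, site_scale_sd²))`.  Defaults 0.5 and 0.1.  Because the
  noise SD inside a site is `g_s`, the injected effect sizes `d_j`, `m_j`
  are in within-site SD units by construction.
* **Effects.** The diagnosis effect is small and distributed
  (default d = 0.2 on 20 of 157 features); the medication effect is larger
  (default d = 0.5 on 30 features).  The two supports are disjoint so the
  effects are separable in ground truth.  Covariate loadings
  `a_j ~ N(0, 0.01²)` per year of age and `b_j ~ N(0, 0.1²)` for sex make
  the covariates genuinely predictive of the features.
* **Site sizes** are log-uniform on `site_size_range` (default 12–250,
  46 sites), reproducing the heavy size skew of pooled consortia; every
  site hosts both classes (case fraction 0.527 by default).
* **Medication structure.** A configurable fraction of sites
  (`site_medication_purity`) is exclusively medicated or exclusively
  unmedicated (alternating), the rest assign medication per patient with
  probability `medicated_fraction`.  This is the lever that aligns a
  clinical variable with site.
* **Medication–duration coupling.** Illness duration is Gaussian
  (mean 9 y, SD 5 y) with a mean gap between medicated and unmedicated
  patients solved in closed form from the target point-biserial
  correlation (default −0.094):
  `D = r·s / sqrt(p·q·(1−r²))`.  The group draws are centered exactly on
  their analytic means, so the realized gap carries no Monte-Carlo error;
  only the clipping of duration into `[0.25, age − 4]` perturbs the
  realized correlation (measured: within ±0.03 of the target on cohorts
  of ≥2000).  Age of onset is `age − duration`; Y-BOCS severity is
  `round(N(25, 6))` clipped to `[0, 40]`, independent of the features.
* **Missingness.** Feature cells are masked MCAR at `missing_rate`
  (default 1%), and a `heavy_missing_fraction` (default 5%) of subjects
  gets a masked fraction drawn from U(0.12, 0.30) — strictly above the 10%
  exclusion threshold, emulating the subjects a consortium drops.

A `GroundTruth` sidecar (affected indices, effect vectors, site
offsets/scales, clean feature matrix) makes every expected group
difference recomputable, which is how the parameter-recovery tests work.

**What the generator does not emulate:** inter-regional covariance
(features are conditionally independent given site and covariates),
non-Gaussian ROI distributions, site-specific age ranges or sex ratios,
informative (non-MCAR) missingness, and scanner effects that interact with
diagnosis.  Passing tests therefore demonstrate that the *machinery*
behaves correctly under the stated structure, not that any real cohort is
classifiable.

## Preprocessing

Subjects with strictly more than 10% missing feature cells are excluded
once, globally, before any CV split.  Within each fold, feature medians
and IQRs are computed on observed training cells only; missing cells are
imputed with the train median and every feature is mapped to
`(x − median)/IQR`.  Quartiles use linear interpolation between order
statistics; an IQR of zero falls back to a divisor of one (the feature
stays median-centered).  Age is robust-scaled the same way; sex and site
are one-hot encoded keeping *all* levels (tree and kernel models take the
full encoding; an unseen level encodes as all-zero).  The
confound-regression design, by contrast, drops one reference level per
categorical factor and adds an intercept so it stays full rank.

## Validation designs

* **Site-stratified k-fold.**  Each (site × diagnosis) cell deals its
  members as evenly as possible across the k folds (cell counts differ by
  ≤ 1); remainder units go to the currently least-loaded folds, which
  provably keeps global fold sizes within one of each other.  Assignment
  is randomized under a seed after a stable sort by subject id.
* **Leave-one-site-out.**  One fold per site, deterministic.  A test site
  containing a single class is flagged; such folds contribute scores to
  accuracy-type metrics but are excluded from fold-AUC summaries with a
  logged count (AUC is undefined on one class).
* **Matched-size folds.**  Subjects are dealt cell-by-cell to the fold
  with the largest remaining share of its size target, so the test-size
  multiset equals the LOSO multiset exactly while every fold mixes sites.
* **Repeated within-site k-fold.**  Diagnosis-stratified, independent
  derived seeds per repeat.

## Models

Eleven configurations: linear/RBF SVM (± PCA), L1/L2 logistic regression,
PCA + logistic regression, linear-kernel Gaussian process, random forest,
XGBoost, and a fully connected network with hidden layers (60, 40, 20).
PCA, where enabled, retains the minimal number of components explaining
90% of the training variance.  SVM, logistic regression and XGBoost tune
declared log-spaced grids (C ∈ {0.01, 0.1, 1, 10}; RBF γ = scale
heuristic × {0.1, 1, 10}; XGBoost depth {2, 4, 6} × learning rate
{0.05, 0.1, 0.3} at 200 trees) by inner 5-fold stratified CV maximizing
AUC, then refit on the full training fold.  The forest uses 200 trees
with √p features per split — a recommendation-level setting at which AUC
and importance rankings are stable for cohorts of this size (tests and
drivers that fit hundreds of forests use 50–100 trees, which changes
nothing measurable there).  The Gaussian process uses a dot-product
kernel at default scale.  The network trains with early stopping on a 10%
validation split; class weighting is not applied (the scikit-learn MLP
does not support it, and the cohorts here are near-balanced).

Scores are decision-function margins for SVMs and case-class
probabilities elsewhere; hard labels for the secondary metrics threshold
at 0 and 0.5 respectively.

## Confound control

Per-feature OLS of the scaled brain features on
[intercept | age | sex − reference | site − reference], coefficients
estimated on training rows and subtracted from both training and test
rows.  Residualization runs after robust scaling and before the model fit
(the order is a declared choice; the two orders differ only by the
per-feature affine scaling).  The solver is a thin QR with a rank check
that names collinear columns.  Under LOSO the held-out site has no
indicator and behaves as the reference level — logged prominently, since
the residualized test features then retain that site's offset relative to
the reference.

## Inference

The pooled AUC over test scores concatenated across folds is the primary
statistic (fold-wise AUCs are reported for dispersion; pooling gives a
single well-defined U).  U = AUC·n₁·n₀; the two-sided p-value comes from
exact enumeration of all C(n, n₁) label assignments when n ≤ 12 (midranks,
doubling the smaller tail, capped at 1) and otherwise from the normal
approximation with tie-corrected variance and a 0.5 continuity
correction, matching `scipy.stats.mannwhitneyu(method="asymptotic")`.
The exact and approximate p agree within 0.02 at the enumeration boundary
for tie-free scores; with heavy ties the exact null is so discrete that
no continuous approximation tracks it pointwise, which is a property of
the statistic, not of the implementation.  Confidence intervals use the
Hanley–McNeil variance with normal quantiles, truncated to [0, 1].
Family-wise control is Bonferroni, default divisor 30 (3 CV schemes × 10
classifiers).

## Feature importance

Observed importance is the forest's impurity importance on true labels;
the null refits the forest on B response permutations (the same permuted
label vectors for every feature), giving per-feature
p = (1 + #{null ≥ observed}) / (B + 1) with floor 1/(B+1).  Selection is
Benjamini–Hochberg per fold at q = 0.05; a feature is *consistent* when
selected in strictly more than half the folds.  Only residualized brain
features may enter (a width check enforces it): importance on raw inputs
is dominated by site indicators rather than anatomy.

One arithmetic consequence deserves emphasis: with B = 200 and m = 157
features, the p floor 1/201 ≈ 0.004975 exceeds the BH entry threshold
unless at least ⌈m·p_floor/q⌉ = 16 features sit at the floor.  A panel
with 10 truly informative features therefore selects nothing at B = 200
regardless of effect size; recovering a small informative set at q = 0.05
requires either a smaller panel or B ≳ 1000.  The package exposes both B
and the forest size; the 30-feature demonstration in the tests and in
`analysis/05_feature_importance.py` shows full recovery under the same
machinery.

## Subgroups and sensitivity

Thresholds exactly as printed: Y-BOCS ≤ 24 low / > 24 high severity,
onset < 18 early / ≥ 18 late, duration ≤ 7 short / > 7 long, medication a
single binary.  Patients missing a stratification variable leave that
contrast only.  The correlation screen dispatches point-biserial, phi or
Pearson by variable type (all Pearson on coded values), uses
pairwise-complete rows, and Bonferroni-corrects over the number of
evaluated pairs.  Sensitivity reruns cross a primary contrast with a
correlated variable's split and compare AUCs against the unsplit run;
cells under 50 subjects per class are skipped (below that the AUC CI is
uninformative).  Because splitting shrinks the training set, intersected
AUCs sit below the unsplit AUC by however much the classifier's learning
curve still rises between the cell size and the full size — for the
random forest that deficit is 0.05–0.07 even at ~400 cases per cell and
has nothing to do with the split variable.  The stability analysis
therefore uses L2 logistic regression, whose learning curve is flat at
these sizes, so the measured deltas (≲0.02 at ~200 cases per cell)
isolate the effect of the split itself.

## Reproducibility

One global seed expands into per-stage streams via
`SeedSequence([root, crc32(label), ...])`, reduced mod 2³¹
(`sitelearn._seeds`).  Fold plans serialize to JSON for exact replay;
identical config + seed + input yields bit-identical reports (asserted).

## Problem sizes in tests and drivers

The test-suite and acceptance-script cohorts are desk-scale by design:
null/signal pipelines use n = 600 over 6 sites; the confounded cohorts
use 12 sites with log-uniform sizes 12–250 (n ≈ 800–1100); the
scheme-dispersion comparison averages over three such cohorts because a
single cohort's fold-SD estimate (9–11 folds) is itself noisy; the
sensitivity analysis uses n = 2000 so intersected cells hold 200–300 cases.
These sizes are the smallest at which the asserted orderings stand
clearly above Monte-Carlo noise.

## Known limitations

* Impurity-based importance is biased toward high-variance features;
  all features here are scale-standardized, which removes most of that
  concern but would not on raw tables.
* The Hanley–McNeil CI undercovers slightly for AUC near 1 with small
  classes; the tests compare it against a bootstrap at moderate AUC only.
* The MLP has no class weighting and its early-stopping split is not
  site-stratified.
* `single_site_repeated` reports pool over repeats, so the pooled U
  treats repeated scores of one subject as independent; fold-level
  summaries are unaffected and are what the site-size correlation uses.
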