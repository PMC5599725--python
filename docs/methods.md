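# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions, and the genuinely open design choices the package fixes.

## Dual regression

Stage 1 regresses each time point's volume, flattened over the analysis mask,
on the K template maps plus an intercept (ordinary least squares); stage 2
regresses each in-mask voxel's time series on the K stage-1 time courses plus
an intercept. Dialects of dual regression differ on two points that the
literature leaves open and this package fixes (both isolated behind the
`dualreg` module surface):

- **No variance normalization** of the stage-1 regressors: template maps enter
  in their native scale.
- **z is the per-regressor t-like statistic** β(v)/SE(v), where SE comes from
  the voxel's residual variance and the corresponding diagonal element of
  (XᵀX)⁻¹. An alternative convention standardizes each beta map globally; the
  per-regressor form is used because it matches the stated interpretation of
  z as signal relative to the error term's standard deviation.

Voxels with exactly zero residual (possible on noise-free synthetic data) get
z = sign(β)·z_cap with z_cap = 10; voxels outside the mask get z = 0. The
analysis mask is the union of template supports dilated by one voxel, so the
regressions never see the all-zero background. A consequence of the
two-stage structure worth noting: multiplying a scan by c scales the stage-1
time courses by c, leaves the stage-2 betas unchanged, and leaves z invariant
— z-maps are scale-free.

## Bayesian discriminative-ROI discovery

The published description of the procedure's internals is not available in
enough detail to re-implement verbatim; this module is therefore a concrete,
documented variant with every choice exposed as a configuration key
(`GammaParams`), chosen to be the simplest member of the described family:

- **Score.** Log Bayesian-Dirichlet marginal likelihood of the class column
  given a binary parent (BDeu-type). The Dirichlet prior places
  `alpha_ess / 2` on each class within each parent state (the classic K2
  metric at the default `alpha_ess = 2`). The score equals the log product of
  sequential predictive probabilities (Pólya urn), which the test suite uses
  as an independent oracle, exhaustively for n ≤ 8. The score is symmetric
  under state relabeling — an anti-correlated voxel scores as high as a
  correlated one — so "more aligned with the labels" is *not* monotonically
  ordered by the score; the property that does hold (and is tested
  exhaustively) is that the state vector equal to the label vector attains
  the global maximum.
- **Representative voxel.** Argmax of the voxel-level score over the current
  mask; ties break to the smallest linear (row-major) index, for
  reproducibility rather than any scientific reason.
- **Region growing.** The ROI is the 26-connected component through the
  representative voxel of all voxels whose across-subject binary vector has
  Hamming similarity ≥ `kappa_sim` (default 0.9) with the representative's.
  Whether the original procedure grew regions by vector similarity, score
  contribution, or a Markov-blanket criterion is unknowable from the
  available text; similarity growing was chosen as the simplest rule that
  parcellates the voxel space and depends only on the image data (a property
  the permutation test exploits: ROIs can be cached across permutations).
- **ROI state.** Majority vote: state 1 iff the subject's binary map covers
  ≥ `tau` (default 0.5, ties up) of the ROI.
- **Discretization.** Strictly greater than the threshold ("larger than"),
  so a voxel exactly at threshold is 0. The default threshold grid is 1.00
  to 3.00 in steps of 0.25 (9 values).
- **Validation.** For each candidate ROI, `n_permutations` (default 199)
  label permutations each rerun the *full selection path* — best voxel on the
  permuted labels, its (cached) grown ROI clipped to the current mask,
  majority states, ROI-level score — and p = (1 + #{permuted ≥ observed}) /
  (B + 1). Running the identical selection function on permuted labels makes
  the test exchangeable despite selection; the Monte-Carlo calibration test
  confirms a validated-model rate near the nominal 5% on label-exchangeable
  cohorts (slightly conservative, because discrete scores tie often).
  Iteration stops at the first ROI with p ≥ 0.05 or after `max_rois`
  (default 5).
- **CPT.** Add-1 (Laplace) smoothing: P(c | j) = (N_jc + 1)/(N_j + 2).

## Classifiers

The three families mirror a standard machine-learning-workbench setup on
binary ROI-state features:

- **SVM**: scikit-learn `SVC(kernel="linear", C=1)` (the
  sequential-minimal-optimization default with a degree-1 polynomial kernel).
- **MLP**: one hidden layer of (features + classes) / 2 units. The solver is
  full-batch lbfgs run to convergence (max 1000 iterations): on cohorts of
  this size stochastic optimizers routinely stall at the majority-class
  solution, which would make the MLP column an artifact of the optimizer
  rather than the model class.
- **TREE**: a hand-written C4.5-style tree (`icnmhe.tree`): gain-ratio splits
  restricted to attributes with at least average information gain, and
  error-based pessimistic pruning with confidence factor 0.25 (upper
  binomial confidence bound via the inverse regularized incomplete beta).
  Written by hand because library trees use cost-complexity pruning and raw
  information gain, and the gain-ratio/EBP combination is the behavior being
  emulated. Bit-compatibility with any particular implementation is a
  non-goal; behavioral equivalence on separable fixtures is the test surface.

Cross-validation is stratified 10-fold with fold-pooled predictions (a
single confusion matrix over all held-out folds). Stratification is a
package choice — it guarantees both classes in every training split at these
sample sizes. Cells where no ROI validates are recorded at the
majority-class baseline (accuracy 56.8% for 32/42, sensitivity 0,
specificity 100), keeping the factorial grid complete for the ANOVA.

## Grid statistics

- Classifier comparisons: performance averaged over thresholds within each
  (network, classifier), then two-sided paired t-tests across networks for
  each classifier pair (df = n_networks − 1). Zero-variance difference
  vectors are flagged degenerate and reported as p = 1.
- The factorial analysis is a three-factor fixed-effects ANOVA (threshold,
  classifier, network) with all two-way interactions; with one observation
  per cell the residual is the three-way interaction (df 304 for a
  9 × 3 × 20 grid; main-effect dfs 8 / 2 / 19; interactions 16 / 152 / 38).
- Stability: per network, the fraction of its threshold × classifier cells
  with accuracy **strictly above** 85% ("above" is read strictly); selection
  keeps networks at **or above** the 70% cut (a network at exactly 70.4%
  must survive, so the boundary is inclusive).
- Best thresholds: cells ranked by accuracy, ties broken by sensitivity then
  specificity; all co-optimal thresholds are reported, since plateaus of
  equally perfect cells are common.

## Biomarker evaluation

Integration patterns: N_{D∩ROI} (count of suprathreshold ROI voxels; monotone
non-increasing in the threshold since D shrinks) and FC_{F∩ROI} (mean of the
unthresholded z-map over the ROI). Group tests are pooled-variance t-tests
(Welch is available via scipy directly but the pooled form is the package
convention). Partial correlations residualize both variables on the
covariates (movement, age, gender coded 0/1, education) with an intercept;
p-values use df = n − k − 2. Bonferroni family size defaults to 3 — one test
per representative network for a given clinical measure and pattern — and is
configurable.

## Synthetic cohorts: what they emulate and what they do not

Templates are Gaussian blobs truncated at 10% of peak, centres
rejection-sampled at ≥ 1.5 support radii, which bounds pairwise support
overlap well under 20% — mimicking compact, mostly disjoint canonical network
maps without shipping data. Scans follow the linear mixing model that dual
regression assumes, with i.i.d. Gaussian noise. Defaults are the study
conditions the analysis targets: 32 MHE / 42 NMHE; 20 templates on a
30 × 36 × 30 grid (a coarse stand-in for 3 mm standard space); T = 115
volumes at TR 2.5 s (120 acquired minus 5 discarded); noise SD 0.2; and a
planted deficit that removes the MHE spatial gain completely (δ = 1) on the
core (≥ 50% of peak weight) of one network. The deficit is multiplicative on
spatial gain so it propagates to dual-regression betas exactly as a
connectivity loss.

Clinical scores are drawn per subject as
`base(group) + coef · (integration − 1) + noise`, where integration is the
mean planted gain (1 = intact). Group base means carry half the MHE–NMHE gap
of the published summary table and the coupling coefficients carry the other
half, so at the default δ = 1 group means land on the table values while the
scores remain correlated with the planted connectivity (Child-Pugh coupling
negative: more severe liver disease, less integration). Age, gender,
education and movement (one scalar: mean framewise displacement, log-normal)
are independent of group.

Not emulated: hemodynamics, physiological noise, motion artifacts,
registration error, spatial autocorrelation of noise, partial-volume
structure, or between-subject anatomical variability. Passing tests
therefore demonstrate the *statistical machinery* — recovery of a planted
multiplicative deficit under additive Gaussian noise — not robustness to
real fMRI confounds.

## Problem sizes used in tests

Unit and property tests run on coarse cohorts (grids around 14 × 16 × 14,
2–3 networks, 14–74 subjects, T = 20–40) chosen as the smallest sizes at
which every stage is overdetermined and the planted effect is cleanly
separable; the end-to-end acceptance path runs at the full default scale
(74 subjects, 20 networks, 30 × 36 × 30, T = 115). Null-calibration uses 100
replicate cohorts of 40 subjects on an 8³ grid with 199 permutations each.

## Known limitations

- The discretization treats only the upper tail (z > thr) as informative;
  anti-correlated deficits (pathologically *increased* connectivity) would
  surface as state-0-enriched ROIs but are not planted or tested.
- The permutation test is slightly conservative on small discrete cohorts
  (tied scores count against the model).
- The MLP at these sample sizes is expressive enough to overfit single-ROI
  features; its column is included for parity across classifier families,
  not as a recommendation.
- `run_pipeline` holds one z-stack per network in memory (float32); for the
  default scale this is ~200 MB, fine on a workstation but not optimized
  further.
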