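# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `taskpred`.

## Behavioral model

Tasks are binary (0 = motion, 1 = color). Three graded predictions are
held on each trial *i*:

* `P_cue(i)` — the validity of the probabilistic pre-cue, one of
  {0.2, 0.4, 0.5, 0.6, 0.8};
* `P_int(i) = (1 − α) P_int(i−1) + α T_prev`, a delta rule with learning
  rate α ∈ [0, 1], initialised at 0.5 (unbiased belief) at session start
  and updated after every trial;
* `P_joint(i) = (1 − β) P_int(i) + β P_cue(i)` with cue reliance
  β ∈ [0, 1].

Unsigned prediction errors `PE_x = |T_cur − P_x|` index reactive task-set
updating demand; `|T_prev − P_joint|` is proactive switch demand,
`|P_joint − 0.5|` prediction confidence, and `|P_int − P_cue|` proactive
interference between the two sources.

Two modeling choices were genuinely open and are fixed as follows:

* **Run boundaries.** `P_int` and `T_prev` carry across runs within a
  session (one continuous recursion); only the split-half analysis
  restarts the recursion at 0.5 inside each half. Nothing in the task
  structure resets expectations between runs, so a single recursion is
  the conservative default.
* **First trial.** The first session trial has no predecessor; `T_prev`,
  `PE_prev` and proactive switch demand are undefined (NaN) there and the
  trial never enters a fit.

## Fitting

Candidate RT models are GLMs over subsets of {PE_prev, PE_cue, PE_int}
plus a free intercept, fit separately for color and motion trials (the
task main effect is absorbed by the intercepts, whose defaults differ by
≈130 ms). PE coefficients are constrained non-negative; the convex QP is
solved exactly by enumerating active sets of the ≤3 constrained columns
(each candidate solved by OLS, the feasible minimum-SSE solution is the
global optimum and satisfies the KKT conditions to machine precision).

α is estimated by exhaustive grid search on [0, 1] with step 0.01, ties
broken toward smaller α; it is re-estimated inside each training set
during cross-validation so no test information leaks. β is computed from
the coefficient sums over the two task fits, `β = C_cue / (C_cue +
C_int)`; when both coefficients are zero β is recorded as missing and the
subject is excluded from group summaries with a warning.

Cross-validated scores use chronological run triplets as folds (any run
count divisible by 3 is accepted; others raise). The score is
`N_test · ln(MSE_test)` (natural log) pooled over the three held-out
folds; a degenerate zero test error is floored at 1e-12 before logging.

**Preprocessing.** Error trials and RT outliers beyond subject mean ± 3 SD
(statistics over correct trials) are removed. The default removes the
rows; the pipeline instead masks their RT to NaN (`drop=False`) so the
delta-rule recursion still traverses the full experienced task sequence
while the excluded rows stay out of every fit. The masked mode is
preferred whenever the original sequence is available because dropping
rows distorts `P_int` for all subsequent trials.

## Bayesian model selection

Per-subject log evidences enter a random-effects scheme: model
frequencies are Dirichlet-distributed, inferred by variational Bayes
(prior concentration 1 per model; attribution weights ∝ exp(log-evidence
+ ψ(α_k) − ψ(Σα)); convergence when the largest concentration change
< 1e-8). Exceedance probabilities come from seeded Monte Carlo over the
Dirichlet posterior (default 10⁶ draws). The Bayes omnibus risk compares
the variational free energy of the alternative with the exact null
evidence `Σ_n logsumexp(lme_n) − N ln K`, and protected exceedance
probabilities shrink toward uniform by that risk.

The bridge from cross-validated scores to log evidences is
`log evidence = −score/2` (Gaussian maximum-likelihood identity: the
score is `N ln MSE ∝ −2 log L` up to a model-independent constant). The
underlying evidence approximation is a package convention; any
model-independent affine change of the scores leaves the selection
invariant (tested).

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
are what every test and the acceptance computation run under.

* **Design**: 9 runs × 50 trials; each pre-cue level 10 times per run;
  round(10·p) color trials at level p (so the cue is exactly valid within
  a run); 25 color trials per run; switch/repeat transitions balanced
  25/25 per run, classifying each run's first trial against the previous
  run's last (run 1 against a discarded burn-in task). Sequences come
  from seeded rejection sampling over permutations with a 10⁵-attempt
  cap; the constraints are loose enough that acceptance typically takes
  a handful of attempts.
* **Population**: α ~ Uniform(0.02, 0.93) and β ~ Beta(2, 5.69) (mean
  0.26), matching the ranges and means this modeling framework was
  developed on; C_int = 0.15 s with C_cue = β·C_int/(1 − β) so that the
  generative weights are consistent with the definition of β; intercepts
  0.84 s (motion) and 0.97 s (color); RT noise σ = 0.1 s by default
  (0.05 s in the model-recovery study). RTs are truncated to [0.2, 3] s.
* **Accuracy**: Bernoulli with p = clip(0.97 − 0.2·PE_joint, 0.5, 1),
  giving ≈0.88 mean accuracy. Accuracy is simulated for realistic
  preprocessing but never modeled.
* **Staircase**: two independent noise levels (color, motion) starting at
  0.5, re-evaluated at every 5th trial of the corresponding feature:
  ≤1 error since the last checkpoint → +0.025; no change over the past 4
  checkpoints → −0.1; clamped to [0.1, 0.9]. An update suppressed by the
  clamp counts as "no change". Feature labels are assigned 50/50 at
  random — the main task's counterbalancing carries no content for the
  staircase rules. The simulator reproduces the rules; the ≈87.5%
  accuracy equilibrium of real observers depends on their psychometric
  functions, which an `ObserverModel` only stylises.
* **Volumes**: per-trial 3D maps over a voxel grid with an analysis
  mask; designated ROIs carry `w_v · z(y_t) · snr` (fixed seeded normal
  weight pattern, z-scored variable series) on top of i.i.d. standard
  normal noise; every trial map is mean-centered within the mask,
  emulating the white-matter-mean subtraction applied to single-trial
  estimates. Default SNR 0.5 per voxel — a regime where single
  searchlights detect the signal reliably but voxelwise effects are
  noisy. Haemodynamics, autocorrelated noise, motion and anatomical
  variability are *not* simulated, so passing tests validate the
  analysis machinery, not its robustness to real fMRI artifacts.

## Searchlight MVPA

Searchlights collect masked voxels within a Euclidean radius of 2 voxels
(33 members when complete). Encoding strength is the fold-mean Fisher z
of the correlation between a held-out variable series and its prediction
from voxel activity, using ridge regression with penalty λ = 1 on
predictors standardized by training statistics and an unpenalized
intercept (no penalty value is canonical here; λ = 1 on standardized
predictors is the neutral default and is config-exposed). Perfect
correlations are clipped at |r| = 1 − 1e-12 before the transform; a
training fold with a constant variable is skipped with a warning. The
implementation solves all searchlights of a map in one batched
normal-equations pass; computations run in the dtype of the input
volumes (float32 input halves memory traffic in large simulations, with
map differences ~1e-6).

Group inference: voxelwise one-sample t against 0, one-sided voxel
threshold p < 0.001, cluster-size FWE correction at 0.05 from a
sign-flip permutation null of the maximum suprathreshold cluster size
(26-neighborhood connectivity; both thresholds and the connectivity are
config-exposed). Sign-flipping is self-contained and exact under the
symmetric-null assumption, replacing external correction software.
Cluster p-values use the add-one estimator `(1 + #{null ≥ size})/(1 +
n_perm)`, which keeps the test valid at any permutation count.

Specificity analyses: exclusive masking removes target searchlights
significant in any control map before cluster inference (it can only
remove centers, never add). The mixture search space scans β̃ ∈ {0, 0.1,
…, 1} and keeps searchlights whose maximal group t over the grid exceeds
the uncorrected p < 0.01 threshold — a documented stand-in for an F-map
over the mixture family, which has no unique operational definition. The
random-reliance permutation draws β̃ per subject (independent
Uniform(0, 1) by default; the sampler is injectable), recomputes the ROI
encoding of the pseudo joint prediction, and compares the observed
statistic (ROI-mean strength or largest significant cluster) against the
permutation null; the distance-decay summary correlates each draw's
Euclidean distance from the behavioral β vector with its group-mean
strength.

## Problem sizes

The validation studies run at sizes chosen to exercise every code path
with comfortable statistical margins: behavioral recovery uses 22
subjects × 450 trials (50 replicate cohorts for the error-bound check);
model recovery uses 22 subjects at σ = 0.05 with 10⁶ Dirichlet samples;
MVPA calibration uses a 20³ grid with a radius-7 spherical mask
(~1 400 voxels), 12 subjects × 90 trials, 200 null replicates at 500
sign-flips each; the embedded-signal study adds a radius-2 ROI at
SNR 0.5 with 199 reliance permutations. Permutation defaults in the
library (1 000) are config-exposed and can be raised for production use.

## Known limitations

* The evidence bridge from CV scores is a convention; absolute BOR
  values depend on it, though model ranking is robust to monotone
  rescaling shared by all models.
* Estimating β from non-negative coefficients biases per-subject
  estimates toward the {0, 1} boundary at high noise; the recovery tests
  quantify the resulting error at the default noise levels.
* The volume generator's white-Gaussian noise makes the sign-flip null
  exactly symmetric; real single-trial estimates have heavier tails and
  spatial autocorrelation, for which cluster-extent FWE is only
  approximately calibrated.
* The mixture search space uses a grid-max statistic, not a parametric
  F-test; its uncorrected threshold is meant for defining search regions,
  not for inference.
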