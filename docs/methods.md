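# Methods

## Feature construction

A connectome here is a symmetric 16×16 matrix over the bilateral
nigrostriatal parcellation (RN, SN, STN, CAUD, PUT, GPe, GPi, THAL; left
before right, regions in that order). "Upper triangular part" is read as
the *strict* upper triangle: self-loops are not connections between
regions, and streamline-averaged FA/MD of a self-loop is ill-defined. That
gives C(16,2) = 120 edges per metric and 3 × 120 = 360 features per
subject. Edge enumeration is row-major over (i, j), i < j, fixed in
`longconn.atlas`; any fixed order is statistically equivalent, but ranked
outputs should be matched by (node pair, metric), not by index.

The longitudinal feature is |follow-up − baseline| per edge, per metric —
the sign of change is deliberately discarded, so the classifier sees
magnitudes of reorganization, not directions. Edges with zero streamlines
store FA = MD = 0 (rather than missing), keeping vectors fixed-length and
compatible with the additive L1 treatment. Matrices are accepted when
asymmetric by at most 1e-9 (file round-trip noise) and symmetrized by
averaging; larger asymmetry is an error, never silently repaired.

## Classifier and cross-validation

Default model: logistic regression with L1 penalty, inverse-regularization
C = 1, fit by liblinear's coordinate descent. Hyperparameters are fixed
for all families (L2 logistic, elastic net with mixing 0.5, linear SVM,
100-tree random forest) — no tuning of any kind. Features are z-scored
with statistics from the training fold only (`trainfold_zscore`), so
count-scale features do not dominate the penalty over FA/MD-scale ones;
`scaling="none"` reproduces a raw-feature run, and the choice is recorded
in every report. The linear SVM has no native probabilities; its margin is
squashed through a logistic function (a modelling choice — the score is
monotone in the margin either way).

Folds: stratified k-fold with k defaulting to the positive-class size (21
at the reference design, where test folds hold 2–3 subjects and exactly
one patient each). The assignment is hand-rolled — each class is shuffled
and dealt n_c // k per fold with remainders going to the smallest folds —
because k may exceed the minority class size (k = n gives leave-one-out),
which scikit-learn's StratifiedKFold rejects. Independent-cohort scores
are the unweighted mean of the k fold models' probabilities; averaging
probabilities (not votes or log-odds) is the simplest reading of model
averaging, and the alternatives are monotone-equivalent for thresholding.
Independent subjects are checked to be disjoint from training ids.

## Permutation relevance

Per fold, the same model is refit `n_perm` times on the fold's training
features with the label vector randomly permuted (class counts preserved,
matching the stratified design). The per-feature mean and SD across refits
form the null; relevance is z = |w − mean| / SD. Features with null SD
below 1e-12 are reported as degenerate, never as z = ∞. Per-fold z values
are aggregated across folds by the mean (median and max available; the
rule is recorded on the output table), and aggregate z ≥ 5 flags a
prominent connection.

Two numerical caveats, both established empirically on null cohorts:

- The L1 null weight distribution is a rare-event mixture — a weight is
  exactly 0 in most permutations. Its SD estimate is therefore tail-driven
  and unstable below a few hundred permutations; at 100 permutations the
  5-SD rule's null exceedance rate is ~1.3%, dropping to ~0.7% at 300–1000.
  Use ≥ 300 permutations (default 1000) when the ≤ 1% false-positive
  property matters.
- "SD changes < 20% when doubling n_perm" holds per-feature for dense
  families (L2) already at 100→200 permutations, but for L1 only at ~1000.

## Evaluation

AUC is the Mann–Whitney pair-counting statistic (ties ½), computed via
average ranks. The ROC enumerates every distinct operating point; each
point's representative threshold is the midpoint of the score gap it
occupies (so perfectly separated classes yield the separating-gap
midpoint), and a subject is called positive at or above the threshold. The
operating threshold maximizes sensitivity² + specificity², ties broken
toward the lower threshold (favoring sensitivity — the screening
use-case). A fixed-0.5 report accompanies every ROC-optimal one.

The "confidence interval" is the (5th, 95th) percentile pair — a 90%
percentile interval, labelled as such — over 1000 bootstrap replicates,
each resampling ⌈0.8 n⌉ prediction–label pairs jointly with replacement
(single-class draws are redrawn; class-stratified resampling is
deliberately not the default). ROC bands interpolate each replicate's
curve on a fixed FPR grid.

Covariate adjustment fits logistic regression of group on (score, age,
gender), all standardized, and reports the two-sided Wald p of the score
coefficient. (Quasi-)separation — non-convergence, non-finite SEs, or a
standardized |β| ≥ 10 — triggers a flagged fallback: a ridge-penalized
(α = 0.5) fit with Wald p from the penalized Hessian. Null calibration at
n = 400 is verified by a KS test in the acceptance suite. Scalar clinical
markers are evaluated by the same machinery, auto-flipped so higher means
more diseased (the flip is recorded).

## Subtyping

The threshold from the control/PD ROC — and nothing else — splits the
independent prodromal cohort: score ≥ threshold is subgroup 1 (PD-like; a
subject exactly at a screening threshold should be flagged). Trajectory
summaries are purely descriptive (mean, SD, quartiles, n per subgroup ×
scale × visit); single-subject cells report an undefined SD rather than
imputing, and no significance tests are run at these subgroup sizes.

## Synthetic cohort: what it emulates, what it does not

Defaults mirror the reference design: 30 controls, 21 de-novo PD, 16
prodromal; ages ~N(66, 5); male fractions 19/30, 17/21, 14/16; ~400 days
between scans. Marginals respect each metric's support — counts are
negative-binomial (edge-specific log-normal means, dispersion 8), FA is
logit-normal in [0, 1], MD log-normal around 0.7×10⁻³ mm²/s — and edges
with zero streamlines zero out FA/MD. Follow-up = baseline + change, with
change SD = marginal SD × √(2(1−ρ)), ρ = 0.7 by default.

The disease signal lives *only* in the change: PD-like subjects get a
directed shift of `effect_size` (default 3) change-SDs, plus variance
inflation, on five implanted edges (two streamline-count, three FA, no MD
— degeneration signs: counts and FA down, MD up) within the
pallido-thalamo-striatal circuit. Baseline group differences are
deliberately absent, so a classifier can only succeed by reading
progression. At effect_size = 0 the PD-like change model coincides exactly
with the control one, giving a usable null. Prodromal subjects are PD-like
with probability 11/16 (Bernoulli per subject), optionally with attenuated
effect. Clinical scales are keyed to the nominal group at baseline and to
the latent class for drift (motor scales rise for PD-like subjects, H&Y
stays pinned at 0 for control-like ones).

Three RNG streams (cohort structure, connectome noise, clinical scores)
derive from one master seed; identical config + seed reproduces the cohort
bit-for-bit, and written cohorts round-trip exactly (matrices stored at
full float64 precision).

What a green test does **not** establish: the generator has no site or
scanner effects, no motion confound, no registration error, no correlation
structure between edges beyond the shared edge-profile means, and its
effect sizes are stated choices, not estimates from patient data. Green
acceptance means the *procedure* is correct and well-calibrated on its
stated world — not that the published effect magnitudes are reproduced.

## Known limitations

- Only linear families expose weights; random-forest "weights" are
  impurity importances and are not interrogated by the permutation test in
  the default pipeline.
- The ridge fallback for separated logistic fits is approximate (penalized
  Wald); a Firth fit would be preferable but is not available in the
  supported dependency set.
- Bootstrap resampling is not class-stratified by default; with very small
  classes the percentile interval can be wide and asymmetric.
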