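# Methods

`dfncpm` implements a dynamic functional network connectivity (dFNC)
analysis chain for resting-state component time courses: sliding-window
connectivity estimation, discrete brain-state clustering, dwell-time
statistics, dichotomic sequential pattern mining, and pattern-based
classification — together with a Markov-switching cohort simulator that
gives every stage a ground truth.

## Synthetic cohorts

Each subject is a T × C matrix (default T = 196 volumes at TR = 2 s,
C = 11 network components). A hidden state path s(t) ∈ {1..k} (default
k = 3) evolves at volume resolution as a first-order Markov chain with a
group-specific transition matrix; row t of the data is an independent draw
from N(0, Σ_{s(t)}) plus isotropic noise of standard deviation
`noise_sd` (default 0.2). The initial state is drawn from the chain's
stationary distribution.

State covariances are correlation matrices built from three profiles:

- **hypo** — near-diagonal; every off-diagonal |r| ≤ 0.1 (small seeded
  perturbations of the identity, eigenvalue-checked with jittered retry);
- **hyper** — one-factor model with loading √0.5, so all off-diagonal
  r ≈ 0.5;
- **anticorrelated-block** — two blocks with opposite-signed loadings of
  magnitude √0.35, giving within-block r ≈ +0.35 and cross-block
  r ≈ −0.35.

Factor-model construction guarantees positive definiteness. Profiles are
deliberately well separated so that window-level state recovery is
achievable; real dFNC states are less separable, so recovery rates on
synthetic data are an upper bound on what identical settings achieve on
real data.

Default dynamics use self-transition probabilities of 0.97–0.99, i.e.
mean dwells of roughly 30–100 volumes (60–200 s). This is the regime in
which sliding-window estimates can track states at all — dwells much
shorter than the 26-TR window would leave most windows mixed — and it is
consistent with the multi-window mean dwell times reported for
resting-state dFNC states. The impaired-like default group ("MCI") has an
elevated self-transition for, and inflow into, the hypo-connected state 1,
so its stationary occupancy of state 1 exceeds the control group's.

Per-subject random substreams are keyed by (seed, group index, subject
index), so a subject's data is invariant to cohort size and the whole
cohort is reproducible bit-for-bit from one seed.

Group-unique transition motifs can be injected for classification
experiments: with a per-subject probability, a state subsequence is
written into the hidden path at a uniformly random position, each motif
state held for `dwell_volumes` consecutive volumes. Holds longer than the
window width (default 30 > 26) are needed for the motif to survive
window-level dominant-state extraction.

The generator emulates state-switching covariance structure only: rows
are i.i.d. given the state (no hemodynamic autocorrelation), there is no
scanner drift, motion, or physiological noise, and components are
zero-mean by construction. Passing tests therefore validate the
estimators' logic and statistical behavior, not robustness to fMRI
artifacts.

## Windowed connectivity

Taper: a rectangle of length W (default 26 TR) is discretely convolved
with a unit-area Gaussian of standard deviation σ = 3 TR (truncated at
±4σ), cropped to its central W samples and renormalized to sum 1. The
"alpha = 3" convention of the common dFNC toolchain is read as σ in TR
units.

Window count: starts are 0, 1, 2, … while start + W ≤ T − 1, i.e.
N_w = T − W for step 1 (the window flush with the series end is dropped).
This convention reproduces the canonical 170 windows for T = 196, W = 26;
the more common T − W + 1 convention would give 171.

Per window, columns are centered with the taper weights and the
taper-weighted covariance/correlation is formed. The `pearson` estimator
returns the weighted correlation; `glasso` fits an L1-penalized Gaussian
precision matrix to the window's correlation matrix (standardized input,
so the penalty grid lives on a common scale) and reports partial
correlations ρ_ij = −Θ_ij/√(Θ_ii Θ_jj). At λ = 0 this reduces exactly to
the inverse of the tapered covariance (partial correlations are scale
invariant); at λ ≥ max|r_ij| the precision is diagonal and all partial
correlations are 0.

The penalty λ* is chosen once per subject: for each of 10 random 80/20
splits of the subject's windows, the model is fitted at every grid value
(default 10 points log-spaced on [0.01, 1]) to the mean training-window
correlation and scored by the mean held-out Gaussian log-likelihood
log det Θ − tr(S_w Θ); λ* maximizes the mean score. Grid values that fail
to converge are dropped with a warning; an error is raised only if all
fail.

Estimates are Fisher z-transformed (atanh, |r| clipped at 1 − 1e−7)
before clustering by default, standard practice to make correlation
differences more nearly variance-stable.

## Brain states

Pooled windows from all subjects are clustered with city-block k-means —
implemented as k-medians, because the coordinate-wise median is the
L1-optimal centroid — with k-means++-style seeding adapted to the metric
(next seed drawn proportionally to L1 distance). Five replicates from
distinct seeded initializations are run and the solution with least total
within-cluster distance is kept. Empty clusters are reseeded at the point
farthest from its nearest centroid. States are relabeled 1..k by
descending occupancy so labels are deterministic; which label is the
hypo- or hyper-connected state is a post-hoc mapping by centroid
connectivity strength, as in the usual reporting convention.

k is either fixed (default 3) or chosen by the elbow of a cluster
validity index: total within-cluster distance divided by the sum of
pairwise centroid distances, with k* at the maximum positive second
difference of the curve. When the maximum second difference is below 10 %
of the curve's range the elbow is flagged low-confidence.

Dwell statistics come from a run-length scan of each dominant-state
sequence: fraction of windows per state, mean contiguous run length (in
windows and in seconds = windows × step × TR), transition counts and a
row-normalized transition matrix (rows with no outgoing transitions are
flagged). Both fraction-of-windows and mean-run-length notions of "dwell
time" are reported, since either may be meant by that phrase.

Group comparisons use the pooled-variance (homoscedastic) two-sample
t-test with two-tailed p from the t distribution on n_a + n_b − 2 df,
computable from raw samples or from summary statistics. Uncorrected
p-values are primary (matching common practice for these pairwise
comparisons); a Holm-corrected column is written alongside for
transparency.

## Sequential pattern mining

Dominant-state sequences are run-length compressed by default, so
patterns describe transition structure. This choice matters: under
gap-allowed containment on raw ~170-length sequences, almost every short
pattern is ubiquitous and pattern counts explode; compression keeps the
pattern space interpretable and desk-scale. `--no-compress` preserves the
literal alternative.

A pattern is contained in a sequence if it is a subsequence (order
preserved, gaps allowed); greedy leftmost matching decides containment
exactly. Mining is prefix-projected depth-first enumeration with
antimonotone support pruning; sequence-level support (number of sequences
containing the pattern at least once) is thresholded at
ceil(min_support × n) per group on that group's n, with min_support
defaulting to 0.05. Pattern lengths are bounded by min_length = 2 (a
single state is not a sequential pattern) and max_length = 10
(tractability; no time constraints are otherwise imposed). The miner is
exact: on small instances it is tested to agree, pattern for pattern and
support for support, with exhaustive enumeration of all label tuples.

Dichotomic pattern mining runs the miner on each group separately under
the same spec and partitions the union into unique-to-A, unique-to-B and
shared sets by exact tuple equality; the partition identity
|unique_A| + |unique_B| + |shared| = |A ∪ B| is asserted on every run.

Note that with small groups the absolute support threshold matters:
below 20 sequences per group, min_support 0.05 admits patterns occurring
in a single sequence, which inflates the unique sets with singletons.
Cohorts of ~24+ per group (threshold ≥ 2) behave like the desk-scale
regime the defaults were designed for.

## Classification

Subjects are encoded as binary vectors of pattern containment (one-hot
encoding against a mined pattern set, using the same compression
convention as mining) or as real-valued percent dwell times. Evaluation:
seeded stratified 80/20 train/test split; grid-search hyperparameter
tuning with inner stratified CV on the training split (RF:
n_estimators ∈ {100, 300, 500}, max_depth ∈ {None, 4, 8},
min_samples_leaf ∈ {1, 3}; LDA: shrinkage ∈ {None, auto}, lsqr solver);
held-out metrics on the test split; then 100 repetitions of stratified
10-fold CV on the full cohort with the tuned settings. Each repetition
pools its out-of-fold predictions into one value per metric (accuracy,
AUC from class-1 probability, recall, precision, F1), summarized as mean
and sd across repetitions. Folds are reduced with a warning when the
smaller class has fewer subjects than folds.

Feature importance: mean impurity-decrease across trees for RF; absolute
standardized discriminant coefficients (|coef| × feature sd) for LDA;
both normalized to sum 1, top-10 reported. The two definitions are not
interchangeable and both are emitted, labeled by model.

## Numerical and design choices

- Ties in state assignment break toward the lower label; argsorts use
  stable ordering, so outputs are deterministic given seeds.
- Zero-variance columns inside a window raise an error naming subject,
  window and column rather than silently producing NaNs.
- Degenerate t-tests: zero pooled variance with unequal means yields
  p = 0 with a warning; zero variance with equal means is an error.
- The pipeline writes every intermediate artifact plus a run manifest
  carrying a config hash; reruns with the same config are byte-identical.
- Problem sizes in the test-suite experiments (e.g. 24–30 subjects,
  T = 196, C = 11, and reduced CV repeats in unit tests) are chosen to
  match the desk-scale study design the defaults describe while keeping
  experiments quick to rerun; the full 100×10-fold protocol is exercised
  in the end-to-end discrimination experiment.

## Known limitations

- No temporal autocorrelation or hemodynamics in the generator (an AR(1)
  option would be a natural extension); windowed estimators are
  consistent under the i.i.d.-given-state model by design.
- Gap-allowed containment makes short motif fragments weakly specific:
  a planted motif's discriminative signal concentrates in longer
  patterns. Constrained (max-gap) matching is out of scope.
- The elbow criterion is a heuristic; on structure-free data it still
  returns a k*, flagged low-confidence.
- k-medians can fail to isolate a genuinely rare state (splitting a
  dense state instead); state prevalences below ~10 % of pooled windows
  are not reliably recovered.
- No meta-state or HMM-based state estimation; no multiple-testing
  correction beyond the transparency Holm column.
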