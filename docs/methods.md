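# Methods

`pursuitdecode` re-implements, on fully synthetic data, a computational chain
for asking whether covert attention and overt eye-movement control share
neural substrates: simulate task-dependent cortical currents and MEG-like
sensor recordings, estimate source currents with an artifact-aware
hierarchical Bayesian inverse, decode the pursuit target's position and
velocity with a spatially sparse lagged regression, and quantify how well a
decoder trained under one task condition transfers to the others.  This note
records the models, the parameter choices that matter, and the limits of
what the synthetic experiments can show.

## Experimental protocol being emulated

Five task conditions share one visual display: a target moving sinusoidally
in the horizontal plane at 0.5 or 0.8 Hz with a 20 deg/s peak velocity, which
fixes the amplitudes at 6.37° (0.5 Hz) and 3.98° (0.8 Hz).  In the *control*
condition the subject fixates and ignores the target (visual processing
only); in *covert* pursuit the subject tracks the target with attention while
fixating (visual + attention); in *overt* pursuit the eyes follow the target
(visual + attention + eye-movement control).  A trial is 2 s of fixation, a
2 ± 0.5 s jittered hold, then 4 s of motion; epochs span −0.4 to +4.0 s
around motion onset at 1000 Hz (4401 samples, onset at sample 400).  One
session is 100 trials × 5 tasks.  The sinusoid's starting phase is not a
protocol constraint; we start at the centre moving at peak velocity
(phase 0), configurable.

## Synthetic data generator

The generator's purpose is to *embody the task/function hypothesis in ground
truth*, so that the downstream claim — decoders transfer between tasks
exactly insofar as the tasks share functional populations — is true by
construction and the pipeline's job is to recover it.

**Source space and forward model.** Dipoles (default 500) sit on a jittered
spherical shell (radius ≈ 80 mm) with contiguous region patches: PreCC,
MSFC, LOTC, IPC, Precuneus, V1/V2, plus a task-irrelevant remainder
(default 50%).  Sensors (default 64) form a Fibonacci lattice on a helmet
cap at 110 mm.  The lead field couples each dipole's random unit orientation
to a per-sensor random pickup direction with inverse-square distance decay
— an abstraction, not a conductor model; it preserves what the inverse and
decoder care about (a full-rank linear map with distance-dependent mixing)
and is swappable for an analytic head model.  Nine extra columns model
extra-brain sources: the two eyeballs (±32, 90, −30) mm and the heart
(15, 0, −350) mm — the magnitude of the heart offset follows the head-model
convention of placing it ~35 cm from the head centre — each with three
orthogonal dipole directions.

**Functional subpopulations.** Three populations are drawn from region pools
(visual ⊂ V1/V2 ∪ LOTC, attention ⊂ IPC ∪ Precuneus ∪ MSFC ∪ LOTC, motor ⊂
PreCC; 60% of each pool recruited, so visual and attention overlap in LOTC).
Each member dipole i carries a fixed unit-norm mixing weight (aᵢ, bᵢ) onto
normalised target position and velocity; the encoding never changes across
tasks — only the gain is gated by the task/function table (attention gain is
zero in control, motor gain is zero outside overt).  Currents lead the
target by 100 ms by default (cortex anticipates the stimulus; the value sits
inside the 50–250 ms range reported for pursuit).  A Gaussian visual evoked
transient (peak 0.1 s after onset, σ = 30 ms) loads the visual population in
every task, and all dipoles receive white background noise.

**Amplitudes.** Gains default to visual 10, attention 8, motor 30
(pA·m/mm² scale) against background noise of sd 10: per-dipole task-locked
SNR is ~1 for visual/attention and ~3 for eye-movement currents.  Two
considerations fix these: single-trial source currents are individually weak
(decoding should need to pool dipoles), and currents under overt pursuit are
several-fold larger than under covert attention — the motor/attention ratio
produces the precentral overt > covert contrast that the region statistics
and the block ANOVA then detect.  Eye-dipole currents are calibrated well
above cortical scale (gain 400 per degree of eye position; tracking the
target in overt tasks, fixation jitter of sd 0.15° plus Poisson blink
transients otherwise) so that omitting the extra dipoles from the inverse
visibly contaminates cortical estimates.  The cardiac source is a smooth
von-Mises-shaped pulse train (default 1.2 Hz) whose fundamental dominates
its spectrum.

**Trial rejection** marks any trial whose signal exceeds 95% (configurable)
of a recordable range on any channel; synthesis never clips, so spikes enter
only through test fixtures.

## Preprocessing and source estimation

Sensor epochs are linearly detrended per channel (standing in for
reference-sensor DC-drift removal, which has no analogue in the synthetic
system), smoothed with a nine-period centred moving average at the raw rate
(reflection-padded), and decimated to 200 Hz (4401 → 881 samples, onset at
sample 80).

The inverse assumes B = [Ĝ, G_extra]·[Z; J_extra] + ε with Ĝ = G·W: cortical
currents live on a reduced grid (every 4th dipole, mirroring the ~4:1
smoothing of a 20,004 → 5004 dipole source model), and W's columns are
unit-sum spatial Gaussians of width σ = 2× the median nearest-neighbour
distance (the width is a free choice; results are insensitive at desk
scale).  Every source column has precision αⱼ with a Gamma(a₀, b₀ⱼ)
hyperprior (a₀ = 10⁻², weakly informative); the prior mean variance is a
data-scaled baseline magnified ×10 inside the six task-relevant regions
(standing in for an fMRI-derived variance prior) and ×100 for the nine
extra-brain columns (artifacts are large).  Inference is variational Bayes
with exact coordinate updates for q(x) and q(α) and a variational-EM update
of the noise variance, so the evidence lower bound is non-decreasing — an
invariant the tests assert.  Hyperparameters are updated on the pooled
trials of a task; posterior-mean currents are returned per trial.  With
hyperparameter updates disabled the posterior mean reduces exactly to
Tikhonov-regularised least squares, which is the closed-form oracle used in
testing.  The published estimator this emulates is specified behaviourally
(simultaneous cortical + extra-brain estimation under an fMRI-informed
hierarchical prior), not numerically; no equivalence with any particular
implementation is claimed.  Non-convergence within the iteration budget
(default 200, tolerance 10⁻⁶) produces a flagged solution, not an error.

## Sparse decoding (SLiR)

Position and velocity at time t are predicted from currents at 11 lags,
tpred + tau·j samples back for j = 0..10 with tau = 6 samples and tpred = 1
sample at 200 Hz — a −305 to −5 ms window.  (A note on units: the lag
spacing is specified in *samples* of the resampled grid; with a 5 ms sample
this is what makes the printed window arithmetic come out.)  Sparsity is
spatial only: all 11 lag weights of a dipole share one relevance
hyperparameter (grouped ARD), so a dipole is either retained with all taps
free or pruned to exact zeros — never a mix.  Position and velocity are fit
independently with separate relevances, since selected-dipole counts are
reported separately per regressand.

The fit is type-II evidence maximisation on sufficient statistics: MacKay
fixed-point updates α_g = (2a₀ + Σ γᵢ)/(2b₀ + Σ μᵢ²) with near-improper
hyperpriors (a₀ = b₀ = 10⁻¹²), the companion residual/(n − Σγ) noise update,
and convergence judged on the movement of log-relevances.  Pruning uses two
criteria: a group goes to zero when its prior variance falls below 10⁻⁸ of
the largest group's, or (after a 5-iteration burn-in, removing at most the
weakest quarter per iteration) when the variance it can support falls below
1% of the target variance.  The second, absolute criterion is what delivers
strong spatial sparsity: evidence maximisation alone retains
chance-correlated inputs with large-but-finite precisions, and with many
collinear dipoles carrying the same two-dimensional signal the relevances
need the burn-in (and gradual removal) to concentrate before any absolute
judgement is sound.  With relevance updates disabled the fit is exactly
ridge regression — the second closed-form oracle.

Training pools lag-embedded rows across trials; currents are z-scored per
dipole with statistics from the training trials only.  Because
cross-validation refits the same task's trials many times, the per-trial
design Gram matrices are cached and summed per fold, and the z-scoring is
applied to the statistics analytically; training rows may be thinned by a
stride (predictions always use every sample).

## Evaluation machinery

Same-task performance uses tenfold cross-validation over trials; cross-task
cells train on all trials of one task and test on all trials of another.
Two scores are computed per test trial and averaged: Pearson r (temporal
shape only — affine-invariant) and the determination coefficient
R² = 1 − SS_res/SS_tot (shape *and* amplitude; unbounded below).  Averaging
per-trial coefficients is a choice — the alternative, scoring the
concatenated series, is available via `aggregate=`.  A decoder that selected
no dipoles predicts a constant; such predictions score r = 0 by convention
inside the matrix (the bare `correlation_coefficient` still raises on
zero-variance input).

Cross-task scores are normalised by the same-task score on the *test* task's
data (the achievable ceiling on that test set); normalising by the training
task's diagonal is available since either reading is defensible.  Normalised
scores classify as high (≥ 0.6), middle (≥ 0.2), or low (< 0.2).
Significance uses a permutation null that shuffles the trial correspondence
between predicted and true series and circularly shifts each predicted
series (preserving within-trial autocorrelation), with
p = (1 + #{null ≥ obs})/(1 + n_perm) and exact enumeration when fewer than
100 distinct permutations exist; families of cells are corrected by
Benjamini–Hochberg.  Selected-dipole sets are categorised by sharing pattern
(exclusive per task; the covert pair; the overt pair; covert/overt at each
frequency; ≥3 tasks); two-task combinations involving control go to a
residual category so fractions sum to one.

The time-lag sweep regresses the target on currents shifted over a lag grid
(instantaneous multivariate regression, half the trials for training and
half for testing).  One caveat discovered in building it: for a *purely
sinusoidal* target with mixed position/velocity encodings, the lag is
unidentifiable in steady state — any shift is absorbed by re-mixing the two
quadratures — so identifiability rests entirely on the motion-onset edge and
the evoked transient.  Trial-averaged currents make that edge information
usable; the sweep recovers the injected 100 ms lead to the grid resolution.

## Group statistics

Randomized-block (within-subject) one- and two-way ANOVA with every effect
tested against its own block interaction: treatment df (a−1, (a−1)(n−1)),
interaction df ((a−1)(b−1), (a−1)(b−1)(n−1)) — for 5 tasks × 6 blocks,
F(4, 20); for the 5×5 two-way design, F(16, 80).  The implementation is an
explicit sum-of-squares decomposition, cross-checked in the tests against
statsmodels' repeated-measures ANOVA; Tukey HSD takes the effect's error
mean square and df directly (studentized-range distribution), so it composes
with the within-subject error terms; simple main effects run the one-way
block ANOVA of one factor inside each level of the other.  No sphericity
correction is applied.  p-values across simple effects are reported
uncorrected.

## Workbench

`RunConfig` (YAML-serialisable) fixes the master seed and all stage
parameters; `run_experiment` executes protocol → generator → rejection →
preprocessing → inverse → decoding → generalization matrix → region/ANOVA
statistics and is bit-reproducible given the config.  The decoder consumes
the *reduced* currents Z (the smoothing does not remove information and the
reduced grid is 4× cheaper).  Runs serialise to an HDF5 container with
groups /protocol /truth /sensors /inverse /models /evaluation /stats, the
config embedded as a YAML attribute, and a schema_version attribute;
missing groups on read are reported as flags rather than errors, a
schema-version mismatch is an error.

## Problem sizes and study conditions used in the checks

The automated checks run at deliberately small scale, chosen once: support
recovery uses the canonical 3-active-of-50 fixture (n = 2000 rows, SNR 10,
coefficients bounded away from zero, 20 seeds); the generalization-pattern
study uses 20 replicates of 60 dipoles × 10 trials/task, decoding the
generator's reduced ground-truth currents directly (the decoder consumes
reduced currents in the full pipeline too; the sensor→inverse→decode chain
is exercised separately end-to-end at 80–200 dipoles); training rows are
thinned 3×.  Statistical calibration uses 1000 permutation nulls (199
permutations each) and 2000 ANOVA nulls.

## What passing does and does not show

The generator is linear, Gaussian, stationary within an epoch, and encodes
exactly the hypothesis under test; real MEG has correlated sensor noise,
non-Gaussian artifacts, imperfect forward models, inter-subject variability,
and cortical dynamics far richer than a gain-gated linear encoding.
Passing therefore shows that the *pipeline* is correct and self-consistent —
that it recovers a known generative structure, that its oracles match, that
its tests are calibrated — not that the scientific conclusion holds in real
brains, and none of the original study's subject-level numbers (current
densities, coefficient tables, sharing percentages, F statistics) are
reproduced or compared against.  Other known limitations: the lead field is
not a conductor model; eye artifacts use idealised kinematics rather than
measured EOG waveforms; microsaccades are absent; trial rejection never
fires on clean synthetic data (no real-world range excursions); and the
sparse decoder's absolute pruning threshold (1% of target variance) trades
recall of very weak inputs for interpretable support — inputs contributing
less than that are deliberately invisible to it.
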