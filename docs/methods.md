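# Methods

## Task model

The environment is a deterministic single-step MDP: one start state, four
actions (cities), four terminal states, transition probabilities in {0, 1},
and a bijection between actions and terminal states within a block. The
discount γ is fixed at 1.0: no action follows the terminal state, so
discounting is inert and the successor features of each policy equal the
terminal state's feature triplet. `EnvironmentSpec` validates all of this at
construction.

The printed sets are module constants (`W_TRAIN`, `W_TEST`, `PHI`,
`PERMUTATION_RULES`). The full 8 × 4 reward matrix has training-task argmaxes
at triplets {1, 4} and test-task argmaxes at {2, 3}; these and the 10–20
point test margins are asserted in tests rather than assumed. One printed
source lists the second test weight vector with a missing element; the
consistent form [−1, 1, 1] (used everywhere else) is adopted.

## Scheduler

Each 68-trial block = phase 1 (32 training trials, one fMRI run) + phase 2
(16 training + 20 test trials, a second run). Constraints: equal task counts
per phase; no immediate task repetition (also across the phase boundary);
phase 2 neither starts with a test trial nor contains more than 3 consecutive
test trials; and a predecessor-balance constraint — trials sharing an
SF&GPI-optimal city are preceded equally often by same- and different-optimal
trials.

Two implementation decisions:

* **Balance tolerance.** A phase of n trials has n − 1 predecessor pairs (an
  odd number for both phases), so the per-city same/different counts cannot
  both be exactly equal. The constraint is enforced per phase, first trial
  exempt, as |same − different| ≤ 1 per optimal city — the tightest version
  the parity allows.
* **Two-stage sampling.** Pure rejection sampling over task orders has
  acceptance probability far below 10⁻⁴. Instead the binary optimal-city
  sequence (where the balance constraint lives) is rejection-sampled, and
  tasks are then filled in constructively: inside a contiguous run of
  same-class trials only two tasks are available, so the no-repetition
  constraint forces strict alternation; the only freedom is each run's
  starting task, and choosing starts so that exactly half of the odd-length
  runs begin with each task yields the exact counts. This is fully general
  (no valid ordering is excluded) and generates a block in ~2 ms.

Event timings use the stated distributions: cue 2 s; cue–response delay
truncated-exponential with mean 3.5 s on [3, 10] s; response window 1.5 s;
feedback 2.5 s (training trials only); ITI truncated-exponential mean 3 s on
[2.5, 10] s. The truncated exponential solves for the rate whose *truncated*
mean matches the target (Brent's method) and samples by inverse CDF. Each
run's clock starts 2.5 s before the first cue.

Across blocks, the six permutation rules are used in random order; the first
four city→triplet mappings form a random Latin square (every city meets every
triplet), later blocks are random bijections, and consecutive blocks share no
fixed point. Experiments shorter than 4 blocks must opt out of the coverage
constraint explicitly.

## Agents

All agents are evaluated at convergence; learning dynamics are out of scope
(the generator's exploration window, below, stands in for early learning).
GPI with the full policy set is provably identical to MB here, and a property
test asserts that equivalence on 1,000 random integer tasks in [−3, 3]³ with
matched tie-breaking. Ties are broken uniformly at random under an explicit
RNG (the printed sets contain none, but property tests do). The UVFA agent is
a per-policy minimum-norm least-squares fit of reward on the task vector;
with the printed training tasks (third weight always 0) its closed form is
θ_a = [ɸ_a1, ɸ_a2, 0], and it transfers to test tasks through task-cue
similarity, picking triplets [1, 4, 1, 3] — it agrees with reuse on three
test tasks and with MB on the fourth. A nonlinear UVFA could behave
differently; the linear instantiation is the deliberate, documented choice.

## Behavioral generator

`CohortConfig` defaults are the study conditions: 38 participants, 6 blocks
of 68 trials, omissions and lapses off unless configured. Each participant is
assigned one agent by exact largest-remainder allocation (so small cohorts
match the nominal mix exactly, which makes the analytic reuse-rate oracle in
`expected_reuse_rate` exact rather than approximate). On each answered trial
the choice follows the agent with probability 1 − lapse and is uniform
otherwise; omissions carry no choice and no reward.

Because the city→triplet mapping changes every block, learning restarts each
block: the first `exploration_trials` (default 16) training trials of a block
include a linearly decaying probability of a uniform-random choice, so
per-block learning curves start near the 0.25 chance level and asymptote
before test trials begin. This window also guarantees that decoder training
sees all four cities, as human learners do.

Post-scan gem estimates are the final block's true (permuted) features plus
Gaussian noise (SD `estimate_noise_sd`, default 20 gems — a visually plausible
error for three-digit quantities), clipped to [0, 250] and rounded, with an
optional noise multiplier for the triplets of the suboptimal training
policies; confidence is a noisy decreasing function of the noise level.

What the generator does *not* emulate: sequential reward learning within the
exploration window (it is exploration, not a learning rule), response times,
and individual differences beyond the agent mix and lapse rate. Tests passing
on this generator show the analysis machinery is correct and calibrated, not
that human data would satisfy the same effect sizes.

## Neural generator

Each block yields two runs of TR × voxel data (TR = 1.25 s). Each city has a
fixed standard-normal voxel pattern; the chosen city's pattern enters at
feedback onset (training trials) and at response onset (all answered trials),
and configured policy categories add the corresponding city's pattern at
test-cue onset (`reactivation`), or the three feature-number patterns of the
category's triplet (`feature_reactivation`, 12 distinct numbers). Event
impulses are placed on the nearest TR and convolved with a canonical
double-gamma HRF. The HRF is interpolated from a 16× oversampled grid onto
exact TR multiples (the library's own TR-resolution sampling does not land on
TR multiples) and normalized to unit peak, so `pattern_snr` reads as peak
signal amplitude per unit noise SD; the sampled peak is at 5.0 s = 4 TRs.

Noise is stationary AR(1) Gaussian per voxel (φ = 0.3, unit SD) plus
motion-like confounds: standardized slow sinusoids (periods 40–160 s) with
white-noise jitter, injected into the data through random loadings and
exported alongside, so confound regression has something real to remove.
Voxels carry no geometry; nominal smoothing levels {0, 2, 4} mm map to 1-D
Gaussian kernels with σ = {0, 1, 2} voxels over the voxel index. The
localizer-session generator embeds response-locked target patterns (4 cities
+ 12 numbers) with the same machinery.

## Decoding

Cleaning is nilearn's signal.clean: per-run linear detrend, confound
regression, voxel-wise z-scoring (that order), idempotent within tolerance.
`EvidenceDecoder` is an sklearn-style estimator: `n_subsamples` random
subsamples with equal class counts, each fitted with one-vs-rest L2 logistic
regression; *evidence* is the per-class sigmoid probability averaged across
subsamples and deliberately not normalized across classes; `predict` is its
argmax. Default regularization C = 1.0, configurable.

Decoder training uses only feedback trials (omissions excluded), taking the
volume lag seconds after feedback onset, rounded to the nearest TR. Test
trials are decoded at TR offsets 0..+12 from cue onset (nearest TR) or 0..+6
from response onset (the *earlier* TR, to avoid leaking later response-phase
signal into offset 0). Offsets outside the run are missing values, never
zeros. Leave-one-run-out structure is enforced by construction and asserted
with a spy test; folds whose training runs lack a city class are skipped with
a warning (a small-sample artifact of synthetic cohorts; at the scale of real
data every class has trials).

Category evidence sorts the four city probabilities by the current test
task's reward structure (more/less rewarding training policy, objective best,
remaining — a partition, asserted). To avoid carry-over, a category is
excluded on trials where its city was chosen on the previous trial; fully
excluded categories propagate as missing. The analysis window for averages is
TR +2..+10 (2.5–12.5 s). Prioritization is the window mean of each training
policy category minus the objective best.

### Validation grid

The lag (4/5/6 s) × smoothing (0/2/4 mm) grid scores each combination by the
mean held-out evidence for the chosen city over 3.75–8.75 s after feedback.
One genuine property of this score is worth documenting: it tracks the signal
amplitude captured by the training volume only while the decoder's
probabilities are far from saturation. With separable data and weak
regularization the score is instead dominated by a calibration artifact —
decoders trained on weaker volumes produce higher sigmoid values on the weak
offsets of the window and win the average. Lag-recovery validation therefore
runs in the ridge-dominated regime (C = 0.01), where the selected lag matches
the planted 5 s HRF peak in almost all seeds and never misses by more than
one TR. The grid flags its selection as unstable when the winning margin over
chance is within twice the spread of the nine grid scores.

### Feature decoding

The 12-class decoder trains on response-locked localizer volumes and is
evaluated on test trials. Per category, the probabilities of the three
feature numbers of that policy's triplet are averaged after excluding
numbers equal to an optimal training-task reward (the overlap is {20, 80,
140}, computed, not hard-coded) and numbers of the previously selected
triplet; chance is 1/12.

## Statistics

Holm correction delegates to statsmodels (`multipletests(method="holm")`);
tests compare it against a from-definition step-down oracle. The cluster test
is implemented in-package: per-offset one-sample t against the chance level;
two-sided cluster forming at the t critical value for α = 0.05 (sidedness is
a configurable convention); clusters are maximal contiguous same-sign
supra-threshold runs; mass is the signed t sum; the null is built from random
per-participant sign flips of (data − chance), exploiting that sign flips
leave per-offset sums of squares unchanged so all permuted t statistics
reduce to one matrix product; p = (1 + #{null max |mass| ≥ |mass|}) /
(1 + n_permutations), which cannot be zero. Offsets with (numerically) zero
across-participant variance are skipped with a warning and removed from the
null as well. The default 10,000 permutations match the analysis convention;
calibration tests use 200 permutations × 1,000 simulations and confirm ~5%
family-wise error. MNE's one-sample cluster permutation test serves as an
independent cross-check in the test suite, never as the implementation.

## Pipeline scale

The default `RunConfig` is desk-scale: 12 participants simulated, 8 decoded,
50 voxels, 5 subsamples, 200 permutations — chosen so a full run finishes in
seconds while leaving every inferential step non-trivial (8 participants is
the smallest cohort for which the sign-flip test can reach p < 0.05). All
stages derive their seeds from the config seed; two runs of one config are
byte-identical. Test and acceptance runs use 2-block experiments and 30–50
voxels for the same reason; the generators accept full-scale settings
unchanged.

## Known limitations

* Converged agents only; no trial-by-trial learning model is fitted.
* The linear UVFA is one member of a model family; its test-task choices are
  qualitative, not a unique prediction.
* Synthetic voxels have no spatial structure, so smoothing levels are labels
  for kernel widths, not physical millimetres.
* The generator's reactivation amplitudes are free parameters; recovery tests
  demonstrate sensitivity of the pipeline, not expected human effect sizes.
* The exploratory subgroup split is a fixed threshold (default 0.35) on the
  share of choices reaching triplet 4; the underlying phenomenon is better
  described as a continuum.
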