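# sfgpi

Simulation and analysis pipeline for multi-task policy reuse: theoretical
agent models (successor features & generalized policy improvement, model-based
control, model-free perseveration, linear UVFA), a constrained fMRI task
scheduler, synthetic behavioral and ROI time-series generators, time-resolved
MVPA decoding with leave-one-run-out cross-validation, and cluster-based
permutation statistics.

It is written for computational cognitive neuroscientists who want to study —
or power-analyze — experiments in which people transfer known task solutions
to novel reward functions, and who need every stage (task structure, agent
predictions, behavioral statistics, decoding, inference) runnable end to end
on synthetic data with no external downloads.

## The science in brief

Each trial is a single-step Markov decision process M = (S, A, p, r, γ).
Four actions (cities) lead deterministically to four terminal states, each
carrying a feature triplet ɸ(s) ∈ ℕ³ (gem counts). A task is a weight vector
w ∈ ℤ³ (market values) and the reward is

    r(s) = ɸ(s)ᵀ w

Because episodes are single-step, the successor features of the policy that
reaches state s reduce to ψ^π = ɸ(s), and generalized policy improvement (GPI)
over a stored policy set Π chooses

    π_w = argmax_{π ∈ Π} ψ(π)ᵀ w

With Π restricted to the two policies that are optimal across the four
training tasks (w_train = {[1,−1,0], [−1,1,0], [1,−2,0], [−2,1,0]}), GPI
predicts continued reuse of those policies on the four held-out test tasks
(w_test = {[2,−1,−1], [−1,1,1], [1,−1,1], [1,1,−1]}), reaching feature
triplets [1, 4, 1, 4] — whereas a model-based (MB) agent with a full model
switches to the objectively best options, triplets [3, 2, 2, 3]. The designed
MB-over-GPI reward margin is only 10–20 points per test choice, so reuse is
nearly optimal; a uniform-random agent earns 76.875 points per test choice in
expectation.

The neural side asks whether the reused policies are *prioritized* in cortical
activity at test-cue onset: a one-vs-rest L2 logistic decoder is trained on
feedback-locked volumes of training trials (balanced by random subsampling),
and its per-city probability time courses on test trials are sorted into
policy categories (more/less rewarding training policy, objective best,
remaining). Window-averaged evidence, prioritization contrasts
(training policy − objective best), Spearman brain–behavior correlations, and
one-sample cluster-based sign-flip permutation tests complete the analysis.

## Worked example

```bash
sfgpi all --seed 42 --out-dir demo_out   # or: python -m sfgpi.cli all ...
```

which simulates 6 blocks × 68 trials for 12 participants (75% SF&GPI-like,
25% MB-like agents, 10% lapse rate), analyzes behavior, simulates and decodes
ROI runs for 8 participants with a planted reactivation of the more-rewarding
training policy, and prints:

```
Training: mean reward/choice 43.38 (random baseline -53.91); optimal-choice rate 0.807.
Test: mean reward/choice 158.23 (random baseline 73.25); reuse rate 0.722; more-rewarding rate 0.693.
  test_reward_vs_random: t(22) = 24.23, p = 2.3e-17, Holm p = 7e-17
  reuse_vs_chance: t(11) = 1.89, p = 0.086, Holm p = 0.086
  more_rewarding_vs_chance: t(11) = 3.84, p = 0.0028, Holm p = 0.0055

Decoding window means (chance 0.25): more_rewarding_training 0.394, less_rewarding_training 0.029,
  objective_best 0.132, remaining 0.057, more_minus_best 0.262, less_minus_best -0.102
  cluster TR 2..2: mass -41.3, p = 0.0348
  cluster TR 3..6: mass 77.2, p = 0.0249
```

Reading this output: the cohort learns the training tasks (reward 43 ≫ the
−54 random baseline; 81% optimal choices including the early exploration
phase), keeps reusing training policies on test tasks (72% reuse; 69% of test
choices pick the *more rewarding* of the two reused policies, against a 25%
chance level), and earns 158 points per test choice against a 73-point random
baseline. In the neural stage the planted reactivation is recovered: evidence
for the more-rewarding training policy (0.394) exceeds the 0.25 chance and
the objective-best evidence (prioritization +0.262), and the cluster test
finds a significant positive cluster from TR +3 to +6 after cue onset. The
early negative cluster is the expected signature of the previous-trial
exclusion procedure at cue onset.

Per-stage commands (`sfgpi simulate`, `analyze-behavior`, `decode`, `stats`,
`report`) expose the same machinery; a YAML config drives every parameter and
every stage is seeded, so reruns are byte-identical.

## Library map

| module | contents |
| --- | --- |
| `sfgpi.task` | MDP, printed task/feature sets, reward matrices, block permutations, constrained 68-trial scheduler, BIDS-style events export |
| `sfgpi.agents` | successor features, GPI/MB/MF/UVFA/random agents and theoretical choice profiles |
| `sfgpi.simulate` | behavioral cohort generator, ROI time-series generator (HRF-convolved city patterns, AR(1) noise, confounds), localizer-session generator |
| `sfgpi.behavior` | performance/reuse metrics, random baselines, learning curves, subgroups, estimate errors, t tests |
| `sfgpi.decoding` | cleaning, `EvidenceDecoder` (sklearn-style estimator), time courses, categorization, prioritization, validation grid, feature decoding, brain–behavior correlations |
| `sfgpi.stats` | Holm correction, one-sample cluster-based sign-flip permutation test |
| `sfgpi.pipeline` / `sfgpi.cli` | orchestration, config, logging, report bundle |

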