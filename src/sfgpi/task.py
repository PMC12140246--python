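"""Gem-collector task environment.

A single-step Markov decision process in which each of four actions
(cities) leads deterministically to one terminal state defined by a
triplet of gem counts (the state features, ``phi``).  The reward for a
choice is the dot product of the trial's task weights ``w`` (market
values) with the features of the reached state.  Blocks re-shuffle the
triplet elements with a shared permutation rule and re-map cities to
triplets, preserving the reward structure while changing appearances.

The module owns the printed task/feature sets, reward computation, the
block permutation rules and the constrained pseudo-random trial
scheduler (68 trials per block: a 32-trial training phase followed by a
mixed phase of 16 training and 20 test trials, recorded as two fMRI
runs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "W_TRAIN",
    "W_TEST",
    "PHI",
    "PERMUTATION_RULES",
    "CITIES",
    "FEATURE_NUMBERS",
    "TRAIN_TASK_IDS",
    "TEST_TASK_IDS",
    "EnvironmentSpec",
    "TaskWeights",
    "FeatureTriplet",
    "BlockConfig",
    "TrialSpec",
    "BlockSchedule",
    "RewardMatrix",
    "SchedulingError",
    "default_tasks",
    "default_features",
    "make_environment",
    "compute_reward",
    "build_reward_matrix",
    "apply_block_permutation",
    "generate_block_schedule",
    "generate_experiment",
    "schedule_to_events",
    "truncated_exponential",
]

# Printed experimental sets: four training tasks, four test tasks (market
# values per gem), four feature triplets (gem counts per city).
W_TRAIN: tuple[tuple[int, ...], ...] = ((1, -1, 0), (-1, 1, 0), (1, -2, 0), (-2, 1, 0))
W_TEST: tuple[tuple[int, ...], ...] = ((2, -1, -1), (-1, 1, 1), (1, -1, 1), (1, 1, -1))
PHI: tuple[tuple[int, ...], ...] = (
    (120, 50, 110),
    (90, 80, 190),
    (140, 150, 40),
    (60, 200, 20),
)
#: The six orderings used to shuffle triplet elements between blocks.
PERMUTATION_RULES: tuple[tuple[int, ...], ...] = (
    (1, 2, 3),
    (1, 3, 2),
    (2, 1, 3),
    (2, 3, 1),
    (3, 1, 2),
    (3, 2, 1),
)
CITIES: tuple[str, ...] = ("sydney", "tokyo", "new_york", "london")
#: The 12 distinct gem counts appearing across the four triplets.
FEATURE_NUMBERS: tuple[int, ...] = (20, 40, 50, 60, 80, 90, 110, 120, 140, 150, 190, 200)

TRAIN_TASK_IDS: tuple[str, ...] = ("train_1", "train_2", "train_3", "train_4")
TEST_TASK_IDS: tuple[str, ...] = ("test_1", "test_2", "test_3", "test_4")

# Event timing (seconds).
CUE_DURATION = 2.0
DELAY_MEAN, DELAY_BOUNDS = 3.5, (3.0, 10.0)
RESPONSE_WINDOW = 1.5
FEEDBACK_DURATION = 2.5
ITI_MEAN, ITI_BOUNDS = 3.0, (2.5, 10.0)
RUN_LEAD_IN = 2.5  # blank time before the first cue of a run


class SchedulingError(RuntimeError):
    """No constraint-satisfying trial ordering found within the retry budget."""


@dataclass(frozen=True)
class TaskWeights:
    """A reward function: points per gem for one task (market values)."""

    w: tuple[int, ...]
    role: str  # "train" | "test"
    task_id: str

    def __post_init__(self):
        if len(self.w) != 3:
            raise ValueError("task weights must have length 3")
        if self.role not in ("train", "test"):
            raise ValueError(f"unknown task role {self.role!r}")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass(frozen=True)
class FeatureTriplet:
    """Gem counts of one terminal state (city)."""

    phi: tuple[int, ...]
    triplet_id: int

    def __post_init__(self):
        if len(self.phi) != 3:
            raise ValueError("feature triplet must have length 3")
        if not 1 <= self.triplet_id <= 4:
            raise ValueError("triplet_id must be in 1..4")
        if any(not 0 <= v <= 250 for v in self.phi):
            raise ValueError("feature values must lie in [0, 250]")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.phi, dtype=float)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Deterministic single-step MDP: start state, 4 actions, 4 terminal states."""

    start_state: str
    actions: tuple[str, ...]
    terminal_states: tuple[str, ...]
    transition: dict  # (state, action) -> {next_state: prob}
    discount: float = 1.0

    def __post_init__(self):
        if len(self.actions) != 4 or len(self.terminal_states) != 4:
            raise ValueError("environment requires 4 actions and 4 terminal states")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError("discount must lie in [0, 1]")
        reached = []
        for action in self.actions:
            row = self.transition[(self.start_state, action)]
            if abs(sum(row.values()) - 1.0) > 1e-12:
                raise ValueError("transition rows must sum to 1")
            ones = [s for s, p in row.items() if p == 1.0]
            if len(ones) != 1:
                raise ValueError("each action must lead to exactly one terminal state")
            reached.append(ones[0])
        if sorted(reached) != sorted(self.terminal_states):
            raise ValueError("actions and terminal states must be bijectively linked")

    def next_state(self, action: str) -> str:
        row = self.transition[(self.start_state, action)]
        return max(row, key=row.get)

    @property
    def deterministic(self) -> bool:
        return all(
            set(row.values()) <= {0.0, 1.0} for row in self.transition.values()
        )


@dataclass(frozen=True)
class BlockConfig:
    """Per-block permutation rule and city-to-triplet mapping."""

    permutation_rule: tuple[int, ...]
    city_to_triplet: dict
    block_index: int

    def __post_init__(self):
        if tuple(sorted(self.permutation_rule)) != (1, 2, 3):
            raise ValueError("permutation_rule must be a bijection on {1,2,3}")
        if self.permutation_rule not in PERMUTATION_RULES:
            raise ValueError("permutation_rule must be one of the six listed rules")
        if sorted(self.city_to_triplet) != sorted(CITIES) or sorted(
            self.city_to_triplet.values()
        ) != [1, 2, 3, 4]:
            raise ValueError("city_to_triplet must be a bijection city -> 1..4")

    @property
    def triplet_to_city(self) -> dict:
        return {t: c for c, t in self.city_to_triplet.items()}


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int  # 1..68
    phase: int  # 1 | 2
    trial_type: str  # "train" | "test"
    task_id: str
    feedback: bool
    cue_onset: float
    response_onset: float
    feedback_onset: float
    iti_duration: float

    def __post_init__(self):
        if self.feedback != (self.trial_type == "train"):
            raise ValueError("feedback is shown iff the trial is a training trial")
        if self.phase == 1 and self.trial_type != "train":
            raise ValueError("phase 1 contains only training trials")


@dataclass(frozen=True)
class BlockSchedule:
    trials: tuple[TrialSpec, ...]
    config: BlockConfig
    run_split: tuple[tuple[int, ...], tuple[int, ...]]  # 0-based trial indices per run

    def run_trials(self, run: int) -> tuple[TrialSpec, ...]:
        return tuple(self.trials[i] for i in self.run_split[run])


@dataclass(frozen=True)
class RewardMatrix:
    """Reward for each (task, policy) pair; entry (i, j) = w_i . phi_j."""

    rewards: np.ndarray  # 4 x 4
    task_axis: tuple[str, ...]
    policy_axis: tuple[int, ...]

    def reward(self, task_id: str, triplet_id: int) -> float:
        return float(
            self.rewards[self.task_axis.index(task_id), self.policy_axis.index(triplet_id)]
        )

    def best_policy(self, task_id: str, within: tuple[int, ...] | None = None) -> int:
        """Argmax triplet for a task, optionally restricted to a policy subset."""
        row = self.rewards[self.task_axis.index(task_id)]
        candidates = self.policy_axis if within is None else tuple(within)
        return max(candidates, key=lambda t: row[self.policy_axis.index(t)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rewards, index=list(self.task_axis), columns=list(self.policy_axis))


def default_tasks(role: str | None = None) -> list[TaskWeights]:
    """The eight printed tasks (4 training + 4 test), or one subset."""
    train = [
        TaskWeights(w, "train", tid) for w, tid in zip(W_TRAIN, TRAIN_TASK_IDS)
    ]
    test = [TaskWeights(w, "test", tid) for w, tid in zip(W_TEST, TEST_TASK_IDS)]
    if role == "train":
        return train
    if role == "test":
        return test
    return train + test


def default_features() -> list[FeatureTriplet]:
    return [FeatureTriplet(phi, i + 1) for i, phi in enumerate(PHI)]


def make_environment(config: BlockConfig | None = None, discount: float = 1.0) -> EnvironmentSpec:
    """Build the single-step MDP; cities map to triplet states per the block config."""
    mapping = (
        config.city_to_triplet
        if config is not None
        else {c: i + 1 for i, c in enumerate(CITIES)}
    )
    transition = {
        ("start", city): {f"state_{mapping[city]}": 1.0} for city in CITIES
    }
    terminal = tuple(f"state_{i}" for i in range(1, 5))
    return EnvironmentSpec(
        start_state="start",
        actions=CITIES,
        terminal_states=terminal,
        transition=transition,
        discount=discount,
    )


def compute_reward(w, phi) -> float:
    """Reward r(s) = phi(s)^T w for one task / terminal state pair."""
    wv = w.vector if isinstance(w, TaskWeights) else np.asarray(w, dtype=float)
    pv = phi.vector if isinstance(phi, FeatureTriplet) else np.asarray(phi, dtype=float)
    if wv.shape != (3,) or pv.shape != (3,):
        raise ValueError("w and phi must both be 3-vectors")
    return float(wv @ pv)


def build_reward_matrix(
    task_set: list[TaskWeights], feature_set: list[FeatureTriplet]
) -> RewardMatrix:
    if len(task_set) != 4 or len(feature_set) != 4:
        raise ValueError("a reward matrix requires 4 tasks and 4 feature triplets")
    rewards = np.array(
        [[compute_reward(w, phi) for phi in feature_set] for w in task_set]
    )
    return RewardMatrix(
        rewards=rewards,
        task_axis=tuple(t.task_id for t in task_set),
        policy_axis=tuple(f.triplet_id for f in feature_set),
    )


def full_reward_matrix() -> RewardMatrix:
    """8 x 4 reward table over all printed tasks (train + test)."""
    tasks = default_tasks()
    features = default_features()
    rewards = np.array([[compute_reward(w, phi) for phi in features] for w in tasks])
    return RewardMatrix(
        rewards=rewards,
        task_axis=tuple(t.task_id for t in tasks),
        policy_axis=tuple(f.triplet_id for f in features),
    )


def train_optimal_policies(rm: RewardMatrix | None = None) -> tuple[int, int]:
    """The two triplets that are argmax policies across the training tasks."""
    if rm is None:
        rm = build_reward_matrix(default_tasks("train"), default_features())
    tasks = [t for t in rm.task_axis if t in TRAIN_TASK_IDS] or list(rm.task_axis)
    optima = {rm.best_policy(t) for t in tasks}
    if len(optima) != 2:
        raise ValueError("training design must have exactly two optimal policies")
    return tuple(sorted(optima))  # type: ignore[return-value]


def apply_block_permutation(
    config: BlockConfig,
    tasks: list[TaskWeights],
    features: list[FeatureTriplet],
) -> tuple[list[TaskWeights], list[FeatureTriplet], dict]:
    """Reorder every w and phi with the block's shared permutation rule.

    The same position permutation is applied to tasks and features, so all
    rewards (dot products) are unchanged.  Returns the permuted tasks,
    permuted features, and the block's city -> triplet mapping.
    """
    rule = config.permutation_rule
    idx = [r - 1 for r in rule]
    new_tasks = [replace(t, w=tuple(t.w[i] for i in idx)) for t in tasks]
    new_features = [replace(f, phi=tuple(f.phi[i] for i in idx)) for f in features]
    return new_tasks, new_features, dict(config.city_to_triplet)


# ---------------------------------------------------------------------------
# Timing


def truncated_exponential(
    rng: np.random.Generator, mean: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    """Sample an exponential restricted to [lower, upper] with a given mean.

    The rate is solved by inverse-CDF so that the *truncated* distribution has
    the requested mean; sampling uses the closed-form truncated inverse CDF.
    """
    from scipy.optimize import brentq

    lo, hi = bounds
    if not lo < mean < hi:
        raise ValueError("mean must lie strictly inside the bounds")
    span = hi - lo

    def trunc_mean(lam):
        z = lam * span
        return lo + 1.0 / lam - span * np.exp(-z) / (1.0 - np.exp(-z))

    lam = brentq(lambda l: trunc_mean(l) - mean, 1e-6, 1e3)
    u = rng.random(size)
    # inverse CDF of exp(lam) truncated to [0, span]
    x = -np.log(1.0 - u * (1.0 - np.exp(-lam * span))) / lam
    return lo + x


# ---------------------------------------------------------------------------
# Trial-order constraints

_SFGPI_OPTIMAL_CACHE: dict | None = None


def sfgpi_optimal_triplet(task_id: str) -> int:
    """The triplet reached by the SF&GPI-optimal action for any printed task.

    For training tasks this is the plain argmax; for test tasks it is the
    argmax restricted to the two train-optimal policies.
    """
    global _SFGPI_OPTIMAL_CACHE
    if _SFGPI_OPTIMAL_CACHE is None:
        features = default_features()
        rm_train = build_reward_matrix(default_tasks("train"), features)
        rm_test = build_reward_matrix(default_tasks("test"), features)
        optima = tuple(sorted({rm_train.best_policy(t) for t in rm_train.task_axis}))
        cache = {t: rm_train.best_policy(t) for t in rm_train.task_axis}
        cache.update(
            {t: rm_test.best_policy(t, within=optima) for t in rm_test.task_axis}
        )
        _SFGPI_OPTIMAL_CACHE = cache
    return _SFGPI_OPTIMAL_CACHE[task_id]


def _no_immediate_repeat(seq: list[str]) -> bool:
    return all(a != b for a, b in zip(seq, seq[1:]))


def _balance_ok(task_seq: list[str]) -> bool:
    """Constraint (3): per optimal-choice value, same- vs different-optimal
    predecessors are balanced (|same - different| <= 1; first trial exempt).

    Exact equality is unattainable for every parity (a phase of n trials has
    n - 1 predecessor pairs), so the tightest satisfiable version is used.
    """
    opt = [sfgpi_optimal_triplet(t) for t in task_seq]
    for value in set(opt):
        same = sum(
            1 for i in range(1, len(opt)) if opt[i] == value and opt[i - 1] == value
        )
        diff = sum(
            1 for i in range(1, len(opt)) if opt[i] == value and opt[i - 1] != value
        )
        if abs(same - diff) > 1:
            return False
    return True


def _max_consecutive(types: list[str], kind: str) -> int:
    best = cur = 0
    for t in types:
        cur = cur + 1 if t == kind else 0
        best = max(best, cur)
    return best


def _balance_letters(letters: np.ndarray) -> bool:
    """|same - different| <= 1 predecessor balance on a binary label sequence."""
    prev, cur = letters[:-1], letters[1:]
    for value in np.unique(letters):
        at = cur == value
        same = int(np.sum(at & (prev == value)))
        diff = int(np.sum(at & (prev != value)))
        if abs(same - diff) > 1:
            return False
    return True


def _runs(positions: list[int]) -> list[list[int]]:
    """Group sorted positions into maximal runs of consecutive integers."""
    runs: list[list[int]] = []
    for p in positions:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def _fill_alternating(
    seq: list, positions: list[int], pair: tuple[str, str], rng: np.random.Generator
) -> None:
    """Assign a task pair (equal counts) to class positions with no adjacent repeats.

    Adjacent trials of the same class carry one of only two tasks, so inside a
    contiguous run the tasks must strictly alternate; the free choice is each
    run's starting task.  Odd-length runs shift the counts by one, so exactly
    half of them start with each task; even runs start at random.
    """
    runs = _runs(positions)
    odd = [r for r in runs if len(r) % 2 == 1]
    starts_first = set(rng.permutation(len(odd))[: len(odd) // 2])
    order = rng.permutation(2)
    for r in runs:
        if len(r) % 2 == 1:
            k = odd.index(r)
            start = pair[order[0]] if k in starts_first else pair[order[1]]
        else:
            start = pair[rng.integers(2)]
        other = pair[0] if start == pair[1] else pair[1]
        for j, pos in enumerate(r):
            seq[pos] = start if j % 2 == 0 else other

# Tasks grouped by the optimal-city label they share (triplet 1 vs triplet 4).
_PHASE1_PAIRS = {"A": ("train_1", "train_3"), "B": ("train_2", "train_4")}
_PHASE2_PAIRS = {
    ("A", "train"): ("train_1", "train_3"),
    ("B", "train"): ("train_2", "train_4"),
    ("A", "test"): ("test_1", "test_3"),
    ("B", "test"): ("test_2", "test_4"),
}


def _sample_phase1(rng: np.random.Generator, retry_budget: int) -> list[str]:
    """32 training trials: equal task counts, no repeats, optimal-choice balance."""
    pool = np.array(["A"] * 16 + ["B"] * 16)
    for _ in range(retry_budget):
        letters = rng.permutation(pool)
        if not _balance_letters(letters):
            continue
        seq: list = [None] * 32
        for letter, pair in _PHASE1_PAIRS.items():
            _fill_alternating(seq, list(np.flatnonzero(letters == letter)), pair, rng)
        return seq
    raise SchedulingError(
        "phase 1: no ordering satisfying the optimal-choice balance constraint "
        f"found in {retry_budget} tries"
    )


def _sample_phase2(
    rng: np.random.Generator, last_phase1_task: str, retry_budget: int
) -> list[str]:
    """16 training + 20 test trials under constraints (1)-(5)."""
    # class labels: (optimal-city letter, trial type)
    pool = np.array(
        [["A", "train"]] * 8 + [["B", "train"]] * 8
        + [["A", "test"]] * 10 + [["B", "test"]] * 10
    )
    for _ in range(retry_budget):
        perm = pool[rng.permutation(len(pool))]
        letters, types = perm[:, 0], perm[:, 1]
        if types[0] == "test":
            continue  # constraint (4): the phase must not begin with a test trial
        if _max_consecutive(list(types), "test") > 3:
            continue  # constraint (5)
        if not _balance_letters(letters):
            continue
        seq: list = [None] * len(perm)
        for (letter, ttype), pair in _PHASE2_PAIRS.items():
            positions = list(np.flatnonzero((letters == letter) & (types == ttype)))
            _fill_alternating(seq, positions, pair, rng)
        if seq[0] == last_phase1_task:
            continue  # no task repetition across the phase boundary
        return seq
    raise SchedulingError(
        "phase 2: no ordering satisfying start/repetition/run-length/balance "
        f"constraints found in {retry_budget} tries"
    )


def _trial_timings(
    rng: np.random.Generator, task_seq: list[str], phase: int, first_index: int
) -> list[TrialSpec]:
    n = len(task_seq)
    delays = truncated_exponential(rng, DELAY_MEAN, DELAY_BOUNDS, n)
    itis = truncated_exponential(rng, ITI_MEAN, ITI_BOUNDS, n)
    trials = []
    t = RUN_LEAD_IN
    for k, task_id in enumerate(task_seq):
        is_train = task_id in TRAIN_TASK_IDS
        cue_onset = t
        response_onset = cue_onset + CUE_DURATION + delays[k]
        feedback_onset = response_onset + RESPONSE_WINDOW
        trials.append(
            TrialSpec(
                trial_index=first_index + k,
                phase=phase,
                trial_type="train" if is_train else "test",
                task_id=task_id,
                feedback=is_train,
                cue_onset=float(cue_onset),
                response_onset=float(response_onset),
                feedback_onset=float(feedback_onset),
                iti_duration=float(itis[k]),
            )
        )
        t = feedback_onset + (FEEDBACK_DURATION if is_train else 0.0) + itis[k]
    return trials


def generate_block_schedule(
    config: BlockConfig,
    seed: int | np.random.Generator,
    retry_budget: int = 10_000,
) -> BlockSchedule:
    """Generate one constraint-satisfying 68-trial block.

    Rejection sampling: shuffle the task multiset until all ordering
    constraints hold (equal task counts are guaranteed by construction).
    Event times are drawn from the stated distributions; each phase is one
    fMRI run with its own clock.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phase1 = _sample_phase1(rng, retry_budget)
    phase2 = _sample_phase2(rng, phase1[-1], retry_budget)
    trials = _trial_timings(rng, phase1, 1, 1) + _trial_timings(rng, phase2, 2, 33)
    return BlockSchedule(
        trials=tuple(trials),
        config=config,
        run_split=(tuple(range(32)), tuple(range(32, 68))),
    )


def _latin_square(rng: np.random.Generator) -> list[dict]:
    """Four bijections city -> triplet covering every (city, triplet) pair once."""
    base = list(rng.permutation([1, 2, 3, 4]))
    rows = [[base[(i + k) % 4] for i in range(4)] for k in range(4)]
    rng.shuffle(rows)
    return [dict(zip(CITIES, row)) for row in rows]


def _mappings_for_blocks(rng: np.random.Generator, n_blocks: int, retry_budget: int) -> list[dict]:
    for _ in range(retry_budget):
        maps = _latin_square(rng)
        while len(maps) < n_blocks:
            perm = list(rng.permutation([1, 2, 3, 4]))
            maps.append(dict(zip(CITIES, perm)))
        maps = maps[:n_blocks]
        ok = all(
            all(a[c] != b[c] for c in CITIES) for a, b in zip(maps, maps[1:])
        )
        if ok:
            return maps
    raise SchedulingError("no city-to-triplet mapping sequence found")


def generate_experiment(
    n_blocks: int = 6,
    seed: int | np.random.Generator = 0,
    retry_budget: int = 10_000,
    require_coverage: bool = True,
) -> list[BlockSchedule]:
    """Generate the block sequence for one participant.

    Block configs satisfy: each city pairs with each triplet at least once
    (needs >= 4 blocks), no city keeps its triplet across consecutive blocks,
    and the six permutation rules are used in randomized order.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if require_coverage and n_blocks < 4:
        raise ValueError(
            "each-city-each-triplet coverage requires at least 4 blocks; "
            "pass require_coverage=False for shorter experiments"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rules = list(rng.permutation(len(PERMUTATION_RULES)))
    while len(rules) < n_blocks:
        rules.append(int(rng.integers(len(PERMUTATION_RULES))))
    if require_coverage:
        mappings = _mappings_for_blocks(rng, n_blocks, retry_budget)
    else:
        mappings = []
        prev = None
        for _ in range(n_blocks):
            for _ in range(retry_budget):
                m = dict(zip(CITIES, rng.permutation([1, 2, 3, 4])))
                if prev is None or all(m[c] != prev[c] for c in CITIES):
                    break
            mappings.append(m)
            prev = m
    schedules = []
    for b in range(n_blocks):
        config = BlockConfig(
            permutation_rule=PERMUTATION_RULES[int(rules[b])],
            city_to_triplet=mappings[b],
            block_index=b + 1,
        )
        schedules.append(generate_block_schedule(config, rng, retry_budget))
    return schedules


def schedule_to_events(schedule: BlockSchedule, block: int | None = None) -> pd.DataFrame:
    """BIDS-style events table: one row per trial, onsets run-relative."""
    block = block if block is not None else schedule.config.block_index
    rows = []
    for run_idx, trial_ids in enumerate(schedule.run_split):
        for i in trial_ids:
            tr = schedule.trials[i]
            rows.append(
                {
                    "onset": tr.cue_onset,
                    "duration": CUE_DURATION,
                    "trial_type": tr.trial_type,
                    "task_id": tr.task_id,
                    "phase": tr.phase,
                    "feedback": tr.feedback,
                    "block": block,
                    "run": 2 * (block - 1) + run_idx + 1,
                    "trial_index": tr.trial_index,
                    "response_onset": tr.response_onset,
                    "feedback_onset": tr.feedback_onset if tr.feedback else np.nan,
                    "iti_duration": tr.iti_duration,
                }
            )
    return pd.DataFrame(rows)
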