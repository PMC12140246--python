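"""Candidate generalization algorithms and their theoretical choice profiles.

Five agents are compared on the gem-collector design:

* **MB** — model-based control with a full model: argmax of the expected
  reward over all four actions.
* **SFGPI** — successor features with generalized policy improvement,
  restricted to the set of optimal training policies.  Because episodes
  are single-step, the successor features of a policy equal the feature
  triplet of its terminal state, and GPI reduces to the argmax of
  ``psi(pi)^T w`` over the retained policy set.
* **MF** — model-free perseveration: reuses the two optimal training
  policies unselectively (0.5 / 0.5) on test tasks.
* **UVFA** — a linear universal value function approximator: per policy,
  a minimum-norm least-squares fit of reward on the task vector,
  generalizing to test tasks through task-cue similarity.
* **RANDOM** — uniform choice among the four actions.

All agents are evaluated at convergence (no learning dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import (
    EnvironmentSpec,
    FeatureTriplet,
    TaskWeights,
    compute_reward,
    default_features,
    default_tasks,
    make_environment,
    train_optimal_policies,
)

AGENT_NAMES = ("MB", "SFGPI", "MF", "UVFA", "RANDOM")

__all__ = [
    "AGENT_NAMES",
    "SuccessorFeatures",
    "AgentChoiceProfile",
    "successor_features",
    "gpi_choice",
    "mb_choice",
    "mf_perseveration_profile",
    "fit_uvfa_linear",
    "uvfa_choice",
    "agent_choice_profile",
]


@dataclass(frozen=True)
class SuccessorFeatures:
    """psi(pi) per policy; equals the terminal triplet in this single-step design."""

    psi: dict  # triplet_id -> np.ndarray (3,)

    def value(self, policy: int, w) -> float:
        wv = w.vector if isinstance(w, TaskWeights) else np.asarray(w, dtype=float)
        return float(self.psi[policy] @ wv)


@dataclass(frozen=True)
class AgentChoiceProfile:
    """Predicted choice probabilities over triplets, one row per task."""

    profile: pd.DataFrame  # index: task_id, columns: triplet ids 1..4
    agent_name: str

    def __post_init__(self):
        arr = self.profile.to_numpy()
        if (arr < -1e-12).any() or not np.allclose(arr.sum(axis=1), 1.0):
            raise ValueError("each profile row must be a probability vector")


def successor_features(
    env: EnvironmentSpec, features: list[FeatureTriplet]
) -> SuccessorFeatures:
    """Converged successor features of the four single-step policies.

    psi^pi(s, a) = sum_{s'} p(s' | s, a) phi(s'), which for a deterministic
    single-step environment is the feature triplet of the terminal state that
    policy pi reaches.  Independent of the discount.
    """
    if not env.deterministic:
        raise ValueError("only deterministic transition structures are supported")
    by_state = {f"state_{f.triplet_id}": f.vector for f in features}
    psi = {}
    for action in env.actions:
        s_next = env.next_state(action)
        triplet_id = int(s_next.rsplit("_", 1)[1])
        psi[triplet_id] = by_state[s_next]
    return SuccessorFeatures(psi=psi)


def _argmax_with_ties(values: dict, rng: np.random.Generator | None) -> int:
    best = max(values.values())
    winners = sorted(k for k, v in values.items() if v == best)
    if len(winners) == 1 or rng is None:
        return winners[0]
    return int(rng.choice(winners))


def gpi_choice(
    w: TaskWeights | np.ndarray,
    policy_set: tuple[int, ...],
    sf: SuccessorFeatures,
    rng: np.random.Generator | None = None,
) -> tuple[int, dict]:
    """Generalized policy improvement: argmax_{pi in Pi} psi(pi)^T w.

    Returns the chosen policy (triplet id) and the valuation restricted to
    the retained set.  Ties are broken uniformly at random when an ``rng``
    is supplied, else by lowest triplet id.
    """
    if len(policy_set) == 0:
        raise ValueError("the retained policy set must be non-empty")
    values = {pi: sf.value(pi, w) for pi in policy_set}
    return _argmax_with_ties(values, rng), values


def mb_choice(
    w: TaskWeights | np.ndarray,
    env: EnvironmentSpec,
    features: list[FeatureTriplet],
    rng: np.random.Generator | None = None,
) -> tuple[int, dict]:
    """Model-based choice: argmax over all four actions of Q_w(s, a)."""
    by_id = {f.triplet_id: f for f in features}
    values = {}
    for action in env.actions:
        triplet_id = int(env.next_state(action).rsplit("_", 1)[1])
        values[triplet_id] = compute_reward(w, by_id[triplet_id])
    return _argmax_with_ties(values, rng), values


def mf_perseveration_profile(
    training_optima: tuple[int, ...],
    test_task_ids: tuple[str, ...] | None = None,
) -> AgentChoiceProfile:
    """Unselective reuse: probability 0.5 on each optimal training policy."""
    if len(set(training_optima)) != 2:
        raise ValueError("model-free perseveration requires exactly 2 training optima")
    if test_task_ids is None:
        test_task_ids = tuple(t.task_id for t in default_tasks("test"))
    rows = np.zeros((len(test_task_ids), 4))
    for pi in training_optima:
        rows[:, pi - 1] = 0.5
    return AgentChoiceProfile(
        profile=pd.DataFrame(rows, index=list(test_task_ids), columns=[1, 2, 3, 4]),
        agent_name="MF",
    )


def fit_uvfa_linear(train_pairs: list[tuple]) -> dict:
    """Per-policy minimum-norm linear fit of reward on the task vector.

    ``train_pairs`` holds (task weights, policy id, observed reward) tuples.
    Returns ``{policy_id: theta}`` with Q_hat(a, w) = w^T theta_a.  With the
    printed training tasks (third weight component always 0) the minimum-norm
    solution is theta_a = [phi_a1, phi_a2, 0].
    """
    by_policy: dict[int, list] = {}
    for w, policy, reward in train_pairs:
        wv = w.vector if isinstance(w, TaskWeights) else np.asarray(w, dtype=float)
        by_policy.setdefault(int(policy), []).append((wv, float(reward)))
    thetas = {}
    for policy, rows in by_policy.items():
        W = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        if len({tuple(r) for r in W}) < 2:
            raise ValueError(f"policy {policy}: need >= 2 distinct training tasks")
        if np.linalg.matrix_rank(W) == 0:
            raise ValueError(f"policy {policy}: rank-0 design")
        theta, *_ = np.linalg.lstsq(W, y, rcond=None)
        thetas[policy] = theta
    return thetas


def uvfa_choice(
    w: TaskWeights | np.ndarray,
    thetas: dict,
    rng: np.random.Generator | None = None,
) -> tuple[int, dict]:
    wv = w.vector if isinstance(w, TaskWeights) else np.asarray(w, dtype=float)
    values = {pi: float(wv @ theta) for pi, theta in thetas.items()}
    return _argmax_with_ties(values, rng), values


def _default_uvfa_thetas(
    tasks_train: list[TaskWeights], features: list[FeatureTriplet]
) -> dict:
    pairs = [
        (w, f.triplet_id, compute_reward(w, f)) for w in tasks_train for f in features
    ]
    return fit_uvfa_linear(pairs)


def agent_choice_profile(
    agent: str,
    task_set: list[TaskWeights],
    env: EnvironmentSpec | None = None,
    features: list[FeatureTriplet] | None = None,
    seed: int | None = None,
    temperature: float | None = None,
) -> AgentChoiceProfile:
    """Theoretical choice profile (task x triplet probabilities) for one agent.

    Deterministic agents yield one-hot rows (mass split evenly across exact
    ties); RANDOM yields uniform rows.  A softmax over the agent's valuation
    is applied instead when ``temperature`` is given (default off: the
    theoretical profiles are deterministic).
    """
    agent = agent.upper()
    if agent not in AGENT_NAMES:
        raise ValueError(f"unknown agent {agent!r}; expected one of {AGENT_NAMES}")
    env = env or make_environment()
    features = features or default_features()
    sf = successor_features(env, features)
    optima = train_optimal_policies()
    thetas = _default_uvfa_thetas(default_tasks("train"), features) if agent == "UVFA" else None

    rows = np.zeros((len(task_set), 4))
    for i, w in enumerate(task_set):
        if agent == "RANDOM":
            rows[i] = 0.25
            continue
        if agent == "MF" and w.role == "test":
            for pi in optima:
                rows[i, pi - 1] = 0.5
            continue
        if agent == "MB" or (agent == "MF" and w.role == "train"):
            _, values = mb_choice(w, env, features)
        elif agent == "SFGPI":
            pset = optima if w.role == "test" else tuple(sf.psi)
            # On training tasks the full set is retained (GPI == MB there).
            _, values = gpi_choice(w, pset, sf)
        else:  # UVFA
            if w.role == "train":
                _, values = mb_choice(w, env, features)
            else:
                _, values = uvfa_choice(w, thetas)
        vals = np.full(4, -np.inf)
        for pi, v in values.items():
            vals[pi - 1] = v
        if temperature is not None:
            z = np.exp((vals - np.nanmax(vals[np.isfinite(vals)])) / temperature)
            z[~np.isfinite(z)] = 0.0
            rows[i] = z / z.sum()
        else:
            winners = np.isclose(vals, vals[np.isfinite(vals)].max()) & np.isfinite(vals)
            rows[i, winners] = 1.0 / winners.sum()
    return AgentChoiceProfile(
        profile=pd.DataFrame(
            rows, index=[t.task_id for t in task_set], columns=[1, 2, 3, 4]
        ),
        agent_name=agent,
    )
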