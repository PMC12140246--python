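"""Synthetic behavioral cohorts and ROI fMRI time series.

The generators emulate the statistical structure the downstream analyses
assume, so the whole pipeline runs without any external download:

* :func:`simulate_cohort` produces trial-by-trial choice/omission/reward
  tables for a cohort of agents playing generated block schedules, plus
  post-scan gem-count estimates with confidence ratings.
* :func:`simulate_roi_runs` produces per-run TR x voxel matrices for one
  region of interest, with HRF-convolved city-specific voxel patterns at
  feedback and response events, configurable category reactivation at
  test-cue onset, AR(1) Gaussian noise and motion-like confounds.
* :func:`simulate_session_one` produces localizer-style runs with
  response-locked city and feature-number patterns for decoder training.

Voxels are abstract (no geometry); spatial smoothing levels quoted in mm
map onto 1-D Gaussian kernels over the voxel index at decode time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level import glover_hrf

from . import task as task_mod
from .task import (
    BlockSchedule,
    CITIES,
    FEATURE_NUMBERS,
    PHI,
    TEST_TASK_IDS,
    TRAIN_TASK_IDS,
    full_reward_matrix,
    sfgpi_optimal_triplet,
    train_optimal_policies,
    truncated_exponential,
)

__all__ = [
    "CohortConfig",
    "BehavioralDataset",
    "NeuralConfig",
    "RoiRunData",
    "POLICY_CATEGORIES",
    "policy_categories",
    "simulate_cohort",
    "expected_reuse_rate",
    "simulate_roi_runs",
    "simulate_session_one",
    "participant_choices",
]

#: The four policy categories a test-trial action can fall into.
POLICY_CATEGORIES = (
    "more_rewarding_training",
    "less_rewarding_training",
    "objective_best",
    "remaining",
)

_RM_FULL = None


def _rm():
    global _RM_FULL
    if _RM_FULL is None:
        _RM_FULL = full_reward_matrix()
    return _RM_FULL


def policy_categories(task_id: str) -> dict:
    """Partition of the four triplets into policy categories for a test task.

    ``more/less_rewarding_training`` are the two optimal training policies
    ranked by their reward on this task; ``objective_best`` is the overall
    argmax; ``remaining`` is the leftover policy.
    """
    if task_id not in TEST_TASK_IDS:
        raise ValueError(f"{task_id!r} is not a test task")
    rm = _rm()
    optima = train_optimal_policies()
    more = rm.best_policy(task_id, within=optima)
    less = [p for p in optima if p != more][0]
    best = rm.best_policy(task_id)
    rest = [p for p in (1, 2, 3, 4) if p not in (more, less, best)]
    if len(rest) != 1:
        raise ValueError("policy categories do not form a partition")
    return {
        "more_rewarding_training": more,
        "less_rewarding_training": less,
        "objective_best": best,
        "remaining": rest[0],
    }


# ---------------------------------------------------------------------------
# Behavioral cohort


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (defaults mirror the design)."""

    n_participants: int = 38
    agent_mix: dict = field(default_factory=lambda: {"SFGPI": 1.0})
    lapse_rate: float = 0.0
    omission_rate: float = 0.0
    seed: int = 0
    estimate_noise_sd: float = 20.0  # gem-count units, post-scan estimates
    suboptimal_noise_multiplier: float = 1.0
    exploration_trials: int = 16  # linear decay of random exploration per block

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if abs(sum(self.agent_mix.values()) - 1.0) > 1e-9:
            raise ValueError("agent_mix proportions must sum to 1")
        for name in self.agent_mix:
            if name.upper() not in ("SFGPI", "MB", "MF", "UVFA", "RANDOM"):
                raise ValueError(f"unknown agent {name!r} in agent_mix")
        if not (0 <= self.lapse_rate <= 1 and 0 <= self.omission_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.lapse_rate + self.omission_rate > 1:
            raise ValueError("lapse_rate + omission_rate must not exceed 1")


@dataclass
class BehavioralDataset:
    trials: pd.DataFrame
    estimates: pd.DataFrame
    agents: pd.Series  # participant -> agent label
    config: CohortConfig
    schedules: list

    def write_tsv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
        self.estimates.to_csv(directory / "estimates.tsv", sep="\t", index=False)
        self.agents.rename("agent").to_csv(directory / "agents.tsv", sep="\t")


def _allocate_agents(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Exact largest-remainder allocation of agents to participants."""
    names = sorted(cfg.agent_mix)
    raw = {a: cfg.agent_mix[a] * cfg.n_participants for a in names}
    counts = {a: int(math.floor(raw[a])) for a in names}
    short = cfg.n_participants - sum(counts.values())
    for a in sorted(names, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    agents = [a.upper() for a in names for _ in range(counts[a])]
    rng.shuffle(agents)
    return agents


_UVFA_TEST_CHOICE = None


def _uvfa_test_choices() -> dict:
    global _UVFA_TEST_CHOICE
    if _UVFA_TEST_CHOICE is None:
        from .agents import fit_uvfa_linear, uvfa_choice
        from .task import compute_reward, default_features, default_tasks

        pairs = [
            (w, f.triplet_id, compute_reward(w, f))
            for w in default_tasks("train")
            for f in default_features()
        ]
        thetas = fit_uvfa_linear(pairs)
        _UVFA_TEST_CHOICE = {
            w.task_id: uvfa_choice(w, thetas)[0] for w in default_tasks("test")
        }
    return _UVFA_TEST_CHOICE


def _agent_triplet(agent: str, task_id: str, rng: np.random.Generator) -> int:
    """Converged choice (triplet id) of one agent on one task."""
    if agent == "RANDOM":
        return int(rng.integers(1, 5))
    if task_id in TRAIN_TASK_IDS:
        return sfgpi_optimal_triplet(task_id)  # all non-random agents learn these
    if agent == "SFGPI":
        return sfgpi_optimal_triplet(task_id)
    if agent == "MB":
        return _rm().best_policy(task_id)
    if agent == "MF":
        return int(rng.choice(train_optimal_policies()))
    if agent == "UVFA":
        return _uvfa_test_choices()[task_id]
    raise ValueError(f"unknown agent {agent!r}")


def simulate_cohort(cfg: CohortConfig, schedules: list[BlockSchedule]) -> BehavioralDataset:
    """Simulate trial-by-trial choices for a cohort on the given schedules.

    Each participant is assigned one agent.  On every answered trial the
    choice follows the agent with probability ``1 - lapse_rate`` and is
    uniform otherwise; responses are omitted with ``omission_rate``.  Early
    training trials of each block include a linearly decaying exploration
    window so per-block learning curves start near chance (the city-triplet
    mapping changes between blocks, so learning restarts each block).
    """
    rng = np.random.default_rng(cfg.seed)
    agents = _allocate_agents(cfg, rng)
    rm = _rm()
    rows = []
    for p, agent in enumerate(agents, start=1):
        for schedule in schedules:
            block = schedule.config.block_index
            t2c = schedule.config.triplet_to_city
            train_pos = 0  # index among the block's training trials
            for run_idx, trial_ids in enumerate(schedule.run_split):
                run = 2 * (block - 1) + run_idx + 1
                for i in trial_ids:
                    trial = schedule.trials[i]
                    omitted = rng.random() < cfg.omission_rate
                    choice = None
                    if not omitted:
                        explore = False
                        if trial.trial_type == "train" and cfg.exploration_trials > 0:
                            p_explore = max(
                                0.0, 1.0 - train_pos / cfg.exploration_trials
                            )
                            explore = rng.random() < p_explore
                        if explore or rng.random() < cfg.lapse_rate:
                            choice = int(rng.integers(1, 5))
                        else:
                            choice = _agent_triplet(agent, trial.task_id, rng)
                    if trial.trial_type == "train":
                        train_pos += 1
                    reward = (
                        rm.reward(trial.task_id, choice) if choice is not None else np.nan
                    )
                    rows.append(
                        {
                            "participant": p,
                            "agent": agent,
                            "block": block,
                            "run": run,
                            "phase": trial.phase,
                            "trial_index": trial.trial_index,
                            "trial_type": trial.trial_type,
                            "task_id": trial.task_id,
                            "feedback": trial.feedback,
                            "omitted": omitted,
                            "choice_triplet": choice,
                            "choice_city": t2c[choice] if choice is not None else None,
                            "reward": reward,
                            "cue_onset": trial.cue_onset,
                            "response_onset": trial.response_onset,
                            "feedback_onset": trial.feedback_onset
                            if trial.feedback
                            else np.nan,
                            "iti_duration": trial.iti_duration,
                        }
                    )
    trials = pd.DataFrame(rows)
    trials["choice_triplet"] = trials["choice_triplet"].astype("Int64")
    estimates = _simulate_estimates(cfg, schedules[-1], agents, rng)
    return BehavioralDataset(
        trials=trials,
        estimates=estimates,
        agents=pd.Series(agents, index=range(1, cfg.n_participants + 1), name="agent"),
        config=cfg,
        schedules=list(schedules),
    )


def _simulate_estimates(
    cfg: CohortConfig,
    final_schedule: BlockSchedule,
    agents: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Post-scan gem-count estimates for the final block, with confidence."""
    config = final_schedule.config
    idx = [r - 1 for r in config.permutation_rule]
    suboptimal = {2, 3}
    rows = []
    for p in range(1, len(agents) + 1):
        for city in CITIES:
            triplet_id = config.city_to_triplet[city]
            truth = [PHI[triplet_id - 1][i] for i in idx]
            sd = cfg.estimate_noise_sd * (
                cfg.suboptimal_noise_multiplier if triplet_id in suboptimal else 1.0
            )
            for pos, true_val in enumerate(truth, start=1):
                est = float(np.clip(round(true_val + rng.normal(0.0, sd)), 0, 250))
                conf = float(np.clip(rng.normal(85.0 - sd, 10.0), 0, 100))
                rows.append(
                    {
                        "participant": p,
                        "city": city,
                        "triplet_id": triplet_id,
                        "position": pos,
                        "truth": float(true_val),
                        "estimate": est,
                        "confidence": conf,
                    }
                )
    return pd.DataFrame(rows)


def expected_reuse_rate(cfg: CohortConfig) -> float:
    """Analytic expected test-trial reuse rate for a cohort configuration.

    Reuse = choosing either optimal training policy on an answered test
    trial.  Per agent the converged base rate is SFGPI/MF 1, MB 0, UVFA 3/4
    (it picks the objective best policy on one of the four test tasks),
    RANDOM 1/2; a lapse replaces the choice with a uniform draw (reuse 1/2).
    """
    base = {"SFGPI": 1.0, "MF": 1.0, "MB": 0.0, "UVFA": 0.75, "RANDOM": 0.5}
    rng = np.random.default_rng(cfg.seed)
    agents = _allocate_agents(cfg, rng)
    lam = cfg.lapse_rate
    rates = [(1 - lam) * base[a] + lam * 0.5 for a in agents]
    return float(np.mean(rates))


def participant_choices(
    data: BehavioralDataset, participant: int, block: int
) -> list:
    """Per-trial chosen cities for one participant/block, aligned with the schedule."""
    sub = data.trials.query("participant == @participant and block == @block")
    sub = sub.sort_values("trial_index")
    return [c if isinstance(c, str) else None for c in sub["choice_city"]]


# ---------------------------------------------------------------------------
# Neural simulation


@dataclass
class NeuralConfig:
    """Parameters of the ROI time-series generator."""

    n_voxels: int = 60
    tr: float = 1.25
    pattern_snr: float = 1.0  # signal amplitude relative to unit noise SD
    reactivation: dict = field(default_factory=dict)  # category -> amplitude at test cue
    feature_reactivation: dict = field(default_factory=dict)  # category -> amplitude
    response_activation: float = 1.0
    feedback_activation: float = 1.0
    noise_ar1: float = 0.3
    noise_sd: float = 1.0
    n_confounds: int = 6
    confound_strength: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        for amp in list(self.reactivation.values()) + list(
            self.feature_reactivation.values()
        ):
            if amp < 0:
                raise ValueError("reactivation amplitudes must be >= 0")
        if self.response_activation < 0 or self.feedback_activation < 0:
            raise ValueError("activation amplitudes must be >= 0")


@dataclass
class RoiRunData:
    """One functional run of one ROI: TR x voxel data plus metadata."""

    data: np.ndarray  # (n_tr, n_voxels)
    events: pd.DataFrame
    motion_confounds: np.ndarray  # (n_tr, k)
    run_id: int | str
    block_id: int | str
    tr: float = 1.25


def _hrf(tr: float, time_length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma response (peak ~5 s) sampled at exact TR multiples."""
    oversampling = 16
    dense = glover_hrf(tr, oversampling=oversampling, time_length=time_length)
    times = np.linspace(0.0, time_length, len(dense))
    hrf = np.interp(np.arange(0.0, time_length, tr), times, dense)
    return hrf / hrf.max()  # unit peak: pattern_snr is peak amplitude / noise SD


def _ar1_noise(rng, n_tr, n_voxels, phi, sd):
    eps = rng.standard_normal((n_tr, n_voxels)) * sd * np.sqrt(max(1 - phi**2, 1e-12))
    out = np.empty((n_tr, n_voxels))
    out[0] = rng.standard_normal(n_voxels) * sd
    for t in range(1, n_tr):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _confounds(rng, n_tr, tr, k):
    """Motion-like nuisance columns: slow sinusoids plus white noise."""
    t = np.arange(n_tr) * tr
    cols = []
    for _ in range(k):
        period = rng.uniform(40.0, 160.0)
        phase = rng.uniform(0, 2 * np.pi)
        cols.append(np.sin(2 * np.pi * t / period + phase) + 0.1 * rng.standard_normal(n_tr))
    X = np.column_stack(cols)
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    return X


def _make_patterns(rng, keys, n_voxels):
    return {k: rng.standard_normal(n_voxels) for k in keys}


def simulate_roi_runs(
    schedule: BlockSchedule,
    choices: list,
    cfg: NeuralConfig,
    patterns: dict | None = None,
    feature_patterns: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[RoiRunData], dict]:
    """Simulate the two runs of one block for one ROI.

    ``choices`` holds the chosen city per trial (None for omissions),
    aligned with ``schedule.trials``.  Each city has a fixed random voxel
    pattern; the chosen city's pattern enters (HRF-convolved) at feedback
    onset on training trials and at response onset on all answered trials.
    Categories listed in ``cfg.reactivation`` add the corresponding city's
    pattern at test-cue onset; ``cfg.feature_reactivation`` likewise adds
    the three feature-number patterns of the category's triplet.  Additive
    AR(1) Gaussian noise and motion-like confounds complete the data.

    Returns the runs and a ground-truth sidecar (patterns used).
    """
    if len(choices) != len(schedule.trials):
        raise ValueError("choices must align with the schedule's trials")
    rng = rng or np.random.default_rng(cfg.seed)
    patterns = patterns or _make_patterns(rng, CITIES, cfg.n_voxels)
    if feature_patterns is None and cfg.feature_reactivation:
        feature_patterns = _make_patterns(rng, FEATURE_NUMBERS, cfg.n_voxels)
    hrf = _hrf(cfg.tr)
    t2c = schedule.config.triplet_to_city
    c2t = schedule.config.city_to_triplet
    events_all = task_mod.schedule_to_events(schedule)
    by_index = {t.trial_index: c for t, c in zip(schedule.trials, choices)}
    events_all["choice_city"] = events_all["trial_index"].map(by_index)
    events_all["choice_triplet"] = events_all["choice_city"].map(
        lambda c: c2t[c] if isinstance(c, str) else np.nan
    )
    runs = []
    for run_idx, trial_ids in enumerate(schedule.run_split):
        trials = [schedule.trials[i] for i in trial_ids]
        run_choices = [choices[i] for i in trial_ids]
        last = trials[-1]
        duration = (
            last.feedback_onset
            + (task_mod.FEEDBACK_DURATION if last.feedback else 0.0)
            + last.iti_duration
            + 15.0
        )
        n_tr = int(np.ceil(duration / cfg.tr))

        def _add(key, onset, amp, store):
            idx = int(round(onset / cfg.tr))
            if 0 <= idx < n_tr:
                store.setdefault(key, np.zeros(n_tr))[idx] += amp

        city_imp: dict = {}
        feat_imp: dict = {}
        for trial, city in zip(trials, run_choices):
            if city is not None:
                _add(city, trial.response_onset, cfg.response_activation, city_imp)
                if trial.feedback:
                    _add(city, trial.feedback_onset, cfg.feedback_activation, city_imp)
            if trial.trial_type == "test":
                cats = policy_categories(trial.task_id)
                for category, amp in cfg.reactivation.items():
                    _add(t2c[cats[category]], trial.cue_onset, amp, city_imp)
                for category, amp in cfg.feature_reactivation.items():
                    for num in PHI[cats[category] - 1]:
                        _add(num, trial.cue_onset, amp, feat_imp)
        data = np.zeros((n_tr, cfg.n_voxels))
        for key, imp in city_imp.items():
            bold = np.convolve(imp, hrf)[:n_tr]
            data += cfg.pattern_snr * bold[:, None] * patterns[key][None, :]
        for key, imp in feat_imp.items():
            bold = np.convolve(imp, hrf)[:n_tr]
            data += cfg.pattern_snr * bold[:, None] * feature_patterns[key][None, :]
        data += _ar1_noise(rng, n_tr, cfg.n_voxels, cfg.noise_ar1, cfg.noise_sd)
        conf = _confounds(rng, n_tr, cfg.tr, cfg.n_confounds)
        loadings = rng.normal(0.0, cfg.confound_strength, (cfg.n_confounds, cfg.n_voxels))
        data += conf @ loadings
        block = schedule.config.block_index
        run_events = events_all[events_all["run"] == 2 * (block - 1) + run_idx + 1]
        runs.append(
            RoiRunData(
                data=data,
                events=run_events.reset_index(drop=True),
                motion_confounds=conf,
                run_id=2 * (block - 1) + run_idx + 1,
                block_id=block,
                tr=cfg.tr,
            )
        )
    truth = {"patterns": patterns, "feature_patterns": feature_patterns}
    return runs, truth


def simulate_session_one(
    cfg: NeuralConfig,
    n_trials_per_target: int = 3,
    seed: int | None = None,
    n_runs: int = 2,
    patterns: dict | None = None,
    feature_patterns: dict | None = None,
) -> tuple[list[RoiRunData], dict]:
    """Localizer-style runs: response-locked city and feature-number patterns.

    Each run presents every target (4 cities + 12 feature numbers)
    ``n_trials_per_target`` times in shuffled order; the target's pattern is
    embedded at response onset.  Labels live in the events tables
    (``trial_type`` in {"city", "number"}, ``target``).
    """
    if n_trials_per_target < 2:
        raise ValueError("need at least 2 trials per target for cross-validation")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    patterns = patterns or _make_patterns(rng, CITIES, cfg.n_voxels)
    feature_patterns = feature_patterns or _make_patterns(rng, FEATURE_NUMBERS, cfg.n_voxels)
    hrf = _hrf(cfg.tr)
    targets = list(CITIES) + [str(n) for n in FEATURE_NUMBERS]
    runs = []
    for r in range(n_runs):
        order = [t for t in targets for _ in range(n_trials_per_target)]
        rng.shuffle(order)
        n = len(order)
        delays = truncated_exponential(rng, 3.0, (1.5, 10.0), n)
        itis = truncated_exponential(rng, 2.0, (1.5, 10.0), n)
        rows = []
        t = task_mod.RUN_LEAD_IN
        for k, target in enumerate(order):
            cue_onset = t
            response_onset = cue_onset + 0.5 + delays[k]
            rows.append(
                {
                    "onset": cue_onset,
                    "duration": 0.5,
                    "trial_type": "city" if target in CITIES else "number",
                    "target": target,
                    "response_onset": response_onset,
                }
            )
            t = response_onset + 1.5 + 0.5 + itis[k]
        events = pd.DataFrame(rows)
        n_tr = int(np.ceil((t + 15.0) / cfg.tr))
        data = np.zeros((n_tr, cfg.n_voxels))
        imp: dict = {}
        for row in rows:
            idx = int(round(row["response_onset"] / cfg.tr))
            if idx < n_tr:
                imp.setdefault(row["target"], np.zeros(n_tr))[idx] += 1.0
        for target, series in imp.items():
            pat = patterns[target] if target in CITIES else feature_patterns[int(target)]
            bold = np.convolve(series, hrf)[:n_tr]
            data += cfg.pattern_snr * bold[:, None] * pat[None, :]
        data += _ar1_noise(rng, n_tr, cfg.n_voxels, cfg.noise_ar1, cfg.noise_sd)
        conf = _confounds(rng, n_tr, cfg.tr, cfg.n_confounds)
        data += conf @ rng.normal(0.0, cfg.confound_strength, (cfg.n_confounds, cfg.n_voxels))
        runs.append(
            RoiRunData(
                data=data,
                events=events,
                motion_confounds=conf,
                run_id=f"localizer_{r + 1}",
                block_id="localizer",
                tr=cfg.tr,
            )
        )
    return runs, {"patterns": patterns, "feature_patterns": feature_patterns}
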