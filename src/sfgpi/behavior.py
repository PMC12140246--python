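"""Behavioral statistics: performance, choice profiles, reuse, learning curves.

All per-choice means exclude omitted trials for human/agent cohorts; the
matched random baseline instead substitutes 0 points on trials the
equivalent participant omitted (a deliberate, documented asymmetry of the
analysis convention being reproduced).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import BehavioralDataset, policy_categories
from .task import (
    RewardMatrix,
    TEST_TASK_IDS,
    full_reward_matrix,
    sfgpi_optimal_triplet,
    train_optimal_policies,
)

__all__ = [
    "ParticipantMetrics",
    "RandomBaseline",
    "score_performance",
    "random_baseline",
    "choice_profiles",
    "learning_curve",
    "subgroup_split",
    "estimate_error_analysis",
    "compare_groups",
]


@dataclass(frozen=True)
class RandomBaseline:
    """Per-agent mean reward/choice for a matched uniform-random cohort."""

    mean_reward_train: np.ndarray
    mean_reward_test: np.ndarray
    n_agents: int
    seed: int

    @property
    def grand_mean_test(self) -> float:
        return float(np.mean(self.mean_reward_test))

    @property
    def grand_mean_train(self) -> float:
        return float(np.mean(self.mean_reward_train))


#: Column schema of the per-participant metrics table.
ParticipantMetrics = [
    "mean_reward_train",
    "mean_reward_test",
    "optimal_rate_train",
    "reuse_rate_test",
    "more_rewarding_rate_test",
    "conditional_more_rewarding",
    "mb_rate_test",
]


def score_performance(
    data: BehavioralDataset | pd.DataFrame, rm: RewardMatrix | None = None
) -> pd.DataFrame:
    """Per-participant performance and policy-reuse metrics.

    Omitted trials are excluded from all per-choice means.  "More rewarding"
    is defined per test task as the better of the two optimal training
    policies under the reward matrix.
    """
    trials = data.trials if isinstance(data, BehavioralDataset) else data
    rm = rm or full_reward_matrix()
    unknown = set(trials["task_id"]) - set(rm.task_axis)
    if unknown:
        raise ValueError(f"unknown task ids in data: {sorted(unknown)}")
    optima = train_optimal_policies()
    more_by_task = {t: policy_categories(t)["more_rewarding_training"] for t in TEST_TASK_IDS}
    best_by_task = {t: rm.best_policy(t) for t in rm.task_axis}

    answered = trials[~trials["omitted"]].copy()
    answered["choice_triplet"] = answered["choice_triplet"].astype(int)
    out = []
    for p, sub in answered.groupby("participant"):
        train = sub[sub["trial_type"] == "train"]
        test = sub[sub["trial_type"] == "test"]
        reuse = test["choice_triplet"].isin(optima)
        more = test["choice_triplet"].eq(test["task_id"].map(more_by_task))
        optimal_train = train["choice_triplet"].eq(train["task_id"].map(best_by_task))
        mb_test = test["choice_triplet"].eq(test["task_id"].map(best_by_task))
        out.append(
            {
                "participant": p,
                "mean_reward_train": train["reward"].mean(),
                "mean_reward_test": test["reward"].mean(),
                "optimal_rate_train": optimal_train.mean(),
                "reuse_rate_test": reuse.mean(),
                "more_rewarding_rate_test": more.mean(),
                "conditional_more_rewarding": more[reuse].mean() if reuse.any() else np.nan,
                "mb_rate_test": mb_test.mean(),
            }
        )
    return pd.DataFrame(out).set_index("participant")


def random_baseline(
    schedules: list,
    omission_mask: pd.DataFrame | None,
    n_agents: int,
    seed: int = 0,
    rm: RewardMatrix | None = None,
) -> RandomBaseline:
    """Matched cohort of uniform-random agents on the same trials.

    ``omission_mask`` (optional) carries columns participant/block/
    trial_index/omitted for the human cohort; rewards of random choices on
    trials the matched human omitted are replaced with 0 points (and still
    count toward that agent's per-choice mean).
    """
    rng = np.random.default_rng(seed)
    rm = rm or full_reward_matrix()
    trial_rows = [
        (s.config.block_index, t.trial_index, t.task_id, t.trial_type)
        for s in schedules
        for t in s.trials
    ]
    if omission_mask is not None:
        participants = sorted(omission_mask["participant"].unique())
        if len(participants) != n_agents:
            raise ValueError("omission mask must cover exactly n_agents participants")
        omitted_lookup = omission_mask.set_index(["participant", "block", "trial_index"])[
            "omitted"
        ]
    tids = list(rm.task_axis)
    reward_table = {
        (t, j + 1): rm.rewards[tids.index(t), j] for t in tids for j in range(4)
    }
    mean_train = np.empty(n_agents)
    mean_test = np.empty(n_agents)
    for a in range(n_agents):
        rewards = {"train": [], "test": []}
        choices = rng.integers(1, 5, size=len(trial_rows))
        for (block, idx, task_id, ttype), c in zip(trial_rows, choices):
            r = reward_table[(task_id, int(c))]
            if omission_mask is not None and bool(
                omitted_lookup.get((participants[a], block, idx), False)
            ):
                r = 0.0
            rewards[ttype].append(r)
        mean_train[a] = np.mean(rewards["train"])
        mean_test[a] = np.mean(rewards["test"])
    return RandomBaseline(mean_train, mean_test, n_agents, seed)


def choice_profiles(
    data: BehavioralDataset | pd.DataFrame,
    trial_type: str | None = None,
    per_task: bool = False,
) -> pd.DataFrame:
    """Per-participant choice proportions over triplets (answered trials).

    Rows sum to 1.  With ``per_task=True``, proportions are computed per
    (participant, task) for task-level panels.
    """
    trials = data.trials if isinstance(data, BehavioralDataset) else data
    answered = trials[~trials["omitted"]].copy()
    if trial_type is not None:
        answered = answered[answered["trial_type"] == trial_type]
    answered["choice_triplet"] = answered["choice_triplet"].astype(int)
    keys = ["participant", "task_id"] if per_task else ["participant"]
    counts = (
        answered.groupby(keys)["choice_triplet"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[1, 2, 3, 4], fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def learning_curve(data: BehavioralDataset | pd.DataFrame) -> np.ndarray:
    """Mean optimal-choice proportion per within-block training-trial index.

    Returns 48 values (the number of training trials in a block), averaged
    over participants and blocks; omitted trials are excluded.
    """
    trials = data.trials if isinstance(data, BehavioralDataset) else data
    train = trials[trials["trial_type"] == "train"].copy()
    train = train.sort_values(["participant", "block", "trial_index"])
    train["train_pos"] = train.groupby(["participant", "block"]).cumcount()
    train = train[~train["omitted"]]
    optimal = train["choice_triplet"].astype(int).eq(
        train["task_id"].map(sfgpi_optimal_triplet)
    )
    curve = optimal.groupby(train["train_pos"]).mean()
    return curve.reindex(range(48)).to_numpy()


def subgroup_split(profiles: pd.DataFrame, threshold: float = 0.35) -> pd.Series:
    """Label participants "full" vs "partial" recapitulation of policy reuse.

    Participants whose test-trial share of choices to triplet 4 is at least
    ``threshold`` show the full two-policy reuse pattern; the rest
    concentrate on triplet 1 only (partial).
    """
    share = profiles[4] if 4 in profiles.columns else profiles["4"]
    return pd.Series(
        np.where(share >= threshold, "full", "partial"),
        index=profiles.index,
        name="subgroup",
    )


def estimate_error_analysis(
    data: BehavioralDataset,
    metrics: pd.DataFrame | None = None,
) -> dict:
    """Post-scan estimate errors per triplet and their link to policy reuse.

    Mean absolute error is averaged over the three gem numbers per triplet.
    The error for the suboptimal-policy triplets (2 and 3) is rank-correlated
    (Spearman, average ranks for ties) with the more-rewarding reuse rate;
    the same is done for the optimal-policy triplets and both p-values are
    Holm-adjusted as one family.  Degenerate (zero-variance) inputs yield a
    flagged NaN correlation.
    """
    from .stats import holm_adjust

    est = data.estimates
    if ((est["estimate"] < 0) | (est["estimate"] > 250)).any():
        raise ValueError("estimates must lie in [0, 250]")
    est = est.assign(abs_error=(est["estimate"] - est["truth"]).abs())
    errors = (
        est.groupby(["participant", "triplet_id"])["abs_error"].mean().unstack()
    )
    confidence = (
        est.groupby(["participant", "triplet_id"])["confidence"].mean().unstack()
    )
    if metrics is None:
        metrics = score_performance(data)
    reuse = metrics["more_rewarding_rate_test"]
    optima = train_optimal_policies()
    suboptimal = [t for t in (1, 2, 3, 4) if t not in optima]
    rows = []
    for label, cols in (("suboptimal", suboptimal), ("optimal", list(optima))):
        err = errors[cols].mean(axis=1).reindex(reuse.index)
        if err.nunique() <= 1 or reuse.nunique() <= 1:
            rows.append({"triplets": label, "rho": np.nan, "p": np.nan, "degenerate": True})
            continue
        rho, p = sps.spearmanr(err, reuse)
        rows.append({"triplets": label, "rho": rho, "p": p, "degenerate": False})
    corr = pd.DataFrame(rows)
    valid = ~corr["p"].isna()
    corr["p_holm"] = np.nan
    if valid.any():
        corr.loc[valid, "p_holm"] = holm_adjust(corr.loc[valid, "p"].to_numpy())
    return {"errors": errors, "confidence": confidence, "correlations": corr}


def compare_groups(x, y, paired: bool = False) -> tuple[float, float, float]:
    """t test: one-sample (y scalar), paired, or independent two-sample.

    Returns (t, degrees of freedom, two-tailed p).  A zero-variance
    one-sample test against its own mean is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    if np.isscalar(y) or np.ndim(y) == 0:
        if len(x) < 2:
            raise ValueError("need n >= 2")
        if np.std(x, ddof=1) == 0 and np.isclose(np.mean(x), float(y)):
            raise ValueError("zero variance sample equals the tested mean: t undefined")
        res = sps.ttest_1samp(x, float(y))
        return float(res.statistic), float(len(x) - 1), float(res.pvalue)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if np.allclose(x, y):
            return 0.0, float(len(x) - 1), 1.0  # all-zero differences: exact null
        res = sps.ttest_rel(x, y)
        return float(res.statistic), float(len(x) - 1), float(res.pvalue)
    res = sps.ttest_ind(x, y)
    return float(res.statistic), float(len(x) + len(y) - 2), float(res.pvalue)
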