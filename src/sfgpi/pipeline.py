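"""End-to-end orchestration: simulate -> analyze behavior -> decode -> stats.

A single :class:`RunConfig` (serializable to/from YAML) drives every stage
with explicit seeds, so two runs of the same config produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoding, simulate, stats, task

logger = logging.getLogger("sfgpi")

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    out_dir: str = "sfgpi_output"
    seed: int = 0
    n_blocks: int = 6
    n_participants: int = 12
    n_decoded_participants: int = 4  # neural stage is the expensive one
    agent_mix: dict = field(default_factory=lambda: {"SFGPI": 0.75, "MB": 0.25})
    lapse_rate: float = 0.1
    omission_rate: float = 0.02
    estimate_noise_sd: float = 20.0
    n_voxels: int = 50
    pattern_snr: float = 1.0
    reactivation: dict = field(
        default_factory=lambda: {"more_rewarding_training": 0.8}
    )
    lag_seconds: float = 5.0
    smoothing_level: float = 0.0
    n_subsamples: int = 5
    regularization: float = 1.0
    n_permutations: int = 200
    holm_family_size: int | None = None  # default: size of the family tested

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 1 <= self.n_decoded_participants <= self.n_participants:
            raise ValueError(
                "n_decoded_participants must lie in [1, n_participants]"
            )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def _simulate(cfg: RunConfig):
    schedules = task.generate_experiment(cfg.n_blocks, seed=cfg.seed)
    cohort_cfg = simulate.CohortConfig(
        n_participants=cfg.n_participants,
        agent_mix=cfg.agent_mix,
        lapse_rate=cfg.lapse_rate,
        omission_rate=cfg.omission_rate,
        estimate_noise_sd=cfg.estimate_noise_sd,
        seed=cfg.seed + 1,
    )
    dataset = simulate.simulate_cohort(cohort_cfg, schedules)
    return schedules, dataset


@_stage("analyze-behavior")
def _analyze_behavior(cfg: RunConfig, schedules, dataset, out: Path):
    metrics = behavior.score_performance(dataset)
    baseline = behavior.random_baseline(
        schedules,
        dataset.trials[["participant", "block", "trial_index", "omitted"]],
        n_agents=cfg.n_participants,
        seed=cfg.seed + 2,
    )
    profiles = behavior.choice_profiles(dataset, trial_type="test")
    curve = behavior.learning_curve(dataset)
    subgroups = behavior.subgroup_split(profiles)
    estimates = behavior.estimate_error_analysis(dataset, metrics)

    tests = {}
    t, df, p = behavior.compare_groups(
        metrics["mean_reward_test"].to_numpy(), baseline.mean_reward_test
    )
    tests["test_reward_vs_random"] = {"t": t, "df": df, "p": p}
    t, df, p = behavior.compare_groups(metrics["reuse_rate_test"].to_numpy(), 0.5)
    tests["reuse_vs_chance"] = {"t": t, "df": df, "p": p}
    t, df, p = behavior.compare_groups(
        metrics["more_rewarding_rate_test"].to_numpy(), 0.25
    )
    tests["more_rewarding_vs_chance"] = {"t": t, "df": df, "p": p}
    family = cfg.holm_family_size or len(tests)
    pvals = [v["p"] for v in tests.values()]
    padj = stats.holm_adjust(pvals + [1.0] * max(0, family - len(pvals)))[: len(pvals)]
    for (name, entry), adj in zip(tests.items(), padj):
        entry["p_holm"] = float(adj)

    metrics.to_csv(out / "participant_metrics.tsv", sep="\t")
    profiles.to_csv(out / "test_choice_profiles.tsv", sep="\t")
    pd.Series(curve, name="optimal_rate").rename_axis("train_trial").to_csv(
        out / "learning_curve.tsv", sep="\t"
    )
    subgroups.to_csv(out / "subgroups.tsv", sep="\t")
    estimates["correlations"].to_csv(out / "estimate_correlations.tsv", sep="\t", index=False)
    return {
        "behavior_tests": tests,
        "random_baseline": {
            "grand_mean_train": baseline.grand_mean_train,
            "grand_mean_test": baseline.grand_mean_test,
        },
        "mean_metrics": metrics.mean(numeric_only=True).to_dict(),
        "subgroup_counts": subgroups.value_counts().to_dict(),
    }


@_stage("decode")
def _decode(cfg: RunConfig, schedules, dataset, out: Path):
    dec_cfg = decoding.DecodingConfig(
        lag_seconds=cfg.lag_seconds,
        smoothing_level=cfg.smoothing_level,
        n_subsamples=cfg.n_subsamples,
        regularization=cfg.regularization,
        seed=cfg.seed + 3,
    )
    neural_cfg = simulate.NeuralConfig(
        n_voxels=cfg.n_voxels,
        pattern_snr=cfg.pattern_snr,
        reactivation=cfg.reactivation,
        seed=cfg.seed + 4,
    )
    mappings = {s.config.block_index: s.config.city_to_triplet for s in schedules}
    rows = []
    per_offset = []
    for p in range(1, cfg.n_decoded_participants + 1):
        rng = np.random.default_rng(cfg.seed + 100 + p)
        runs = []
        patterns = None
        for schedule in schedules:
            choices = simulate.participant_choices(dataset, p, schedule.config.block_index)
            block_runs, truth = simulate.simulate_roi_runs(
                schedule, choices, neural_cfg, patterns=patterns, rng=rng
            )
            patterns = truth["patterns"]
            runs.extend(block_runs)
        ptc = decoding.decode_test_trials(runs, dec_cfg)
        ce = decoding.categorize_evidence(ptc, mappings)
        means = decoding.window_average(ce, dec_cfg)
        prio = decoding.prioritization(means)
        rows.append({"participant": p, **means.to_dict(), **prio.to_dict()})
        per_offset.append(decoding.timecourse_by_category(ce))
    table = pd.DataFrame(rows).set_index("participant")
    table.to_csv(out / "decoding_window_means.tsv", sep="\t")
    tc = pd.concat(per_offset, keys=range(1, cfg.n_decoded_participants + 1), names=["participant"])
    tc.to_csv(out / "decoding_timecourses.tsv", sep="\t")
    return table, tc


@_stage("stats")
def _stats(cfg: RunConfig, table: pd.DataFrame, tc: pd.DataFrame, out: Path):
    summary = {"window_means": table.mean().to_dict()}
    if len(table) >= 2:
        cluster_cfg = stats.ClusterTestConfig(
            n_permutations=cfg.n_permutations,
            mu0=0.25,
            window=(2, 10),
            seed=cfg.seed + 5,
        )
        more = (
            tc["more_rewarding_training"].unstack("offset").to_numpy()
        )  # participants x offsets
        result = stats.cluster_permutation_one_sample(more, cluster_cfg)
        result.to_frame().to_csv(out / "clusters_more_rewarding.tsv", sep="\t", index=False)
        summary["clusters_more_rewarding"] = result.to_frame().to_dict("records")
    return summary


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns the JSON-serializable summary (also written to summary.json).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg.to_yaml(out / "config.yaml")
        schedules, dataset = _simulate(cfg)
        for schedule in schedules:
            ev = task.schedule_to_events(schedule)
            ev.to_csv(
                out / f"events_block-{schedule.config.block_index:02d}.tsv",
                sep="\t",
                index=False,
            )
        dataset.write_tsv(out / "behavior")
        summary = {
            "seed": cfg.seed,
            "versions": _versions(),
            "behavior": _analyze_behavior(cfg, schedules, dataset, out),
        }
        table, tc = _decode(cfg, schedules, dataset, out)
        summary["neural"] = _stats(cfg, table, tc, out)
        report = out / "summary.json"
        report.write_text(json.dumps(summary, indent=2, default=float))
        _write_report(summary, out / "report.txt")
        logger.info("pipeline complete: %s", report)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _versions() -> dict:
    import nilearn
    import sklearn

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "nilearn": nilearn.__version__,
    }


def _write_report(summary: dict, path: Path) -> None:
    lines = ["Policy-reuse simulation report", "=" * 32, ""]
    b = summary["behavior"]
    m = b["mean_metrics"]
    lines.append(
        f"Training: mean reward/choice {m['mean_reward_train']:.2f} "
        f"(random baseline {b['random_baseline']['grand_mean_train']:.2f}); "
        f"optimal-choice rate {m['optimal_rate_train']:.3f}."
    )
    lines.append(
        f"Test: mean reward/choice {m['mean_reward_test']:.2f} "
        f"(random baseline {b['random_baseline']['grand_mean_test']:.2f}); "
        f"reuse rate {m['reuse_rate_test']:.3f}; "
        f"more-rewarding rate {m['more_rewarding_rate_test']:.3f}."
    )
    for name, t in b["behavior_tests"].items():
        lines.append(
            f"  {name}: t({t['df']:.0f}) = {t['t']:.2f}, p = {t['p']:.2g}, "
            f"Holm p = {t['p_holm']:.2g}"
        )
    if "neural" in summary:
        lines.append("")
        wm = summary["neural"]["window_means"]
        lines.append(
            "Decoding window means (chance 0.25): "
            + ", ".join(f"{k} {v:.3f}" for k, v in wm.items())
        )
        for cl in summary["neural"].get("clusters_more_rewarding", []):
            lines.append(
                f"  cluster TR {cl['start_offset']}..{cl['end_offset']}: "
                f"mass {cl['mass']:.1f}, p = {cl['p_value']:.3g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
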