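"""Holm correction and the one-sample cluster-based sign-flip permutation test.

The cluster test is the inference engine for every time-resolved decoding
contrast: per time point a one-sample t statistic against the chance level,
clusters of contiguous supra-threshold points (same sign), cluster mass =
sum of t within the cluster, and a null distribution of maximal cluster
masses built by randomly sign-flipping each participant's (data - chance)
time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterTestConfig",
    "ClusterResult",
    "holm_adjust",
    "cluster_permutation_one_sample",
]


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class ClusterTestConfig:
    n_permutations: int = 10_000
    alpha_cluster_forming: float = 0.05  # two-sided t threshold
    mu0: float = 0.25  # chance level (0.25 for policies, 1/12 for features)
    window: tuple[int, int] | None = None  # inclusive offset range to test
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha_cluster_forming < 1:
            raise ValueError("alpha_cluster_forming must lie in (0, 1)")


@dataclass
class ClusterResult:
    clusters: list  # (start_offset, end_offset, mass, p_value)
    t_observed: np.ndarray
    offsets: np.ndarray
    threshold: float
    config: ClusterTestConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.clusters, columns=["start_offset", "end_offset", "mass", "p_value"]
        )


def _t_one_sample(centered: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t over participants (axis 0); NaN when variance is 0."""
    n = centered.shape[0]
    mean = centered.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    # essentially-zero variance (identical values up to float residue)
    degenerate = sd <= np.abs(mean) * 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate & (sd > 0), mean / (sd / np.sqrt(n)), np.nan)
    return t


def _clusters_from_t(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous supra-threshold runs of same-signed t; mass = sum t."""
    out = []
    sign = np.zeros(len(t), dtype=int)
    valid = ~np.isnan(t)
    sign[valid & (t > threshold)] = 1
    sign[valid & (t < -threshold)] = -1
    start = None
    for i in range(len(t) + 1):
        cur = sign[i] if i < len(t) else 0
        if start is not None and (i == len(t) or cur != sign[start]):
            out.append((start, i - 1, float(np.sum(t[start:i]))))
            start = None
        if i < len(t) and cur != 0 and start is None:
            start = i
    return out


def cluster_permutation_one_sample(
    data: np.ndarray, cfg: ClusterTestConfig
) -> ClusterResult:
    """One-sample cluster-based permutation test against a chance level.

    ``data`` is participants x time offsets.  Per offset, a one-sample t vs
    ``cfg.mu0`` is computed; clusters form where |t| exceeds the two-sided
    critical t at ``alpha_cluster_forming``.  The null distribution of the
    maximal |cluster mass| is built from ``n_permutations`` random
    per-participant sign flips of (data - mu0); each observed cluster gets
    p = (1 + #{null >= observed}) / (1 + n_permutations).

    Offsets with zero across-participant variance are skipped with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("data must be participants x offsets with >= 2 participants")
    n, n_off = data.shape
    offsets = np.arange(n_off)
    if cfg.window is not None:
        lo, hi = cfg.window
        if lo < 0 or hi >= n_off:
            raise ValueError("window must lie within the data's offsets")
        data = data[:, lo : hi + 1]
        offsets = np.arange(lo, hi + 1)
    centered = data - cfg.mu0
    t_obs = _t_one_sample(centered)
    if np.isnan(t_obs).any():
        warnings.warn(
            "offsets with zero across-participant variance were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        centered = centered.copy()
        centered[:, np.isnan(t_obs)] = 0.0  # drop skipped offsets from the null too
    threshold = float(sps.t.ppf(1 - cfg.alpha_cluster_forming / 2, n - 1))
    observed = _clusters_from_t(t_obs, threshold)

    rng = np.random.default_rng(cfg.seed)
    # Sign flips leave per-offset sums of squares unchanged, so the permuted
    # t statistics reduce to a single matrix product over all permutations.
    signs = rng.choice((-1.0, 1.0), size=(cfg.n_permutations, n))
    sumsq = np.sum(centered**2, axis=0)
    means = signs @ centered / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sumsq - n * means**2) / (n - 1)
        t_perm = np.where(var > 0, means / np.sqrt(var / n), np.nan)
    null_max = np.zeros(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        masses = [abs(m) for *_, m in _clusters_from_t(t_perm[k], threshold)]
        null_max[k] = max(masses, default=0.0)

    clusters = []
    for start, end, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + cfg.n_permutations)
        clusters.append((int(offsets[start]), int(offsets[end]), mass, float(p)))
    return ClusterResult(
        clusters=clusters,
        t_observed=t_obs,
        offsets=offsets,
        threshold=threshold,
        config=cfg,
    )
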