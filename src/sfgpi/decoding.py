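"""Time-resolved MVPA: cleaning, decoder training, evaluation, categorization.

The pipeline mirrors the standard ROI decoding recipe: per-run cleaning
(linear detrend, motion-confound regression, voxel-wise z-scoring), training
of an L2 logistic one-vs-rest decoder on feedback-locked volumes of training
trials with balanced random subsampling, leave-one-run-out evaluation of
per-class probability time courses on test trials (cue- or response-locked),
categorization of the four city probabilities into policy categories, window
averages, prioritization contrasts, a lag x smoothing validation grid, and
12-class feature decoding with reward/previous-trial exclusions.

One-vs-rest probabilities are deliberately left unnormalized (they need not
sum to 1); evidence is the arithmetic mean of probabilities across
subsampling iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.signal import clean as nilearn_clean
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.utils.validation import check_is_fitted

from .simulate import POLICY_CATEGORIES, RoiRunData, policy_categories
from .task import FEATURE_NUMBERS, PHI, TRAIN_TASK_IDS, full_reward_matrix

__all__ = [
    "DecodingConfig",
    "EvidenceDecoder",
    "ProbabilityTimecourse",
    "CategoryEvidence",
    "clean_run",
    "smooth_voxels",
    "train_policy_decoder",
    "train_feature_decoder",
    "decode_timecourse",
    "decode_test_trials",
    "categorize_evidence",
    "window_average",
    "prioritization",
    "validation_grid",
    "feature_evidence",
    "excluded_reward_features",
    "brain_behavior_correlation",
]

CUE_OFFSETS = tuple(range(0, 13))  # TR_0 .. TR_+12 (0-15 s after cue onset)
RESPONSE_OFFSETS = tuple(range(0, 7))  # TR_0 .. TR_+6 locked to response phase


@dataclass
class DecodingConfig:
    """Decoder training / evaluation parameters."""

    lag_seconds: float = 5.0  # volume taken lag seconds after the locking event
    smoothing_level: float = 0.0  # nominal mm; sigma = level / 2 voxels
    n_subsamples: int = 100
    tr: float = 1.25
    window: tuple[int, int] = (2, 10)  # TR offsets averaged (2.5-12.5 s)
    regularization: float = 1.0  # inverse L2 strength (sklearn C)
    seed: int = 0

    def __post_init__(self):
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


class EvidenceDecoder(ClassifierMixin, BaseEstimator):
    """Balanced-subsample one-vs-rest L2 logistic decoder.

    ``fit`` draws ``n_subsamples`` random subsamples with equal class counts
    and fits one one-vs-rest logistic regression per subsample.  ``evidence``
    returns the per-class sigmoid probabilities averaged across subsamples
    (not normalized across classes); ``predict`` is its argmax.

    Parameters
    ----------
    n_subsamples : number of balanced subsampling iterations.
    C : inverse L2 regularization strength.
    random_state : seed for the subsampling.
    """

    def __init__(self, n_subsamples: int = 100, C: float = 1.0, random_state: int = 0):
        self.n_subsamples = n_subsamples
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("decoder training needs at least 2 classes")
        n_min = counts.min()
        if n_min < 1:
            raise ValueError("every class needs at least one training trial")
        rng = np.random.default_rng(self.random_state)
        self.classes_ = classes
        self.estimators_ = []
        self.subsample_size_ = int(n_min)
        for _ in range(self.n_subsamples):
            idx = np.concatenate(
                [
                    rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                    for c in classes
                ]
            )
            # default penalty is L2; C is its inverse strength
            ovr = OneVsRestClassifier(LogisticRegression(C=self.C, max_iter=1000))
            self.estimators_.append(ovr.fit(X[idx], y[idx]))
        return self

    def evidence(self, X) -> np.ndarray:
        """Mean unnormalized per-class probability across subsamples."""
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), len(self.classes_)))
        for ovr in self.estimators_:
            for j, est in enumerate(ovr.estimators_):
                out[:, j] += est.predict_proba(X)[:, 1]
        return out / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.evidence(X), axis=1)]


@dataclass
class ProbabilityTimecourse:
    """Per-trial, per-class decoder evidence at a grid of TR offsets."""

    probs: np.ndarray  # (n_trials, n_offsets, n_classes), NaN out of run
    classes: np.ndarray
    offsets: np.ndarray
    trials: pd.DataFrame  # metadata per decoded trial

    def class_index(self, label) -> int:
        return int(np.flatnonzero(self.classes == label)[0])


@dataclass
class CategoryEvidence:
    """Policy-category evidence per test trial/offset with exclusion masks."""

    evidence: np.ndarray  # (n_trials, n_offsets, 4 categories)
    excluded: np.ndarray  # (n_trials, 4) True where previous-trial overlap
    categories: tuple = POLICY_CATEGORIES
    offsets: np.ndarray | None = None
    trials: pd.DataFrame | None = None


def smooth_voxels(data: np.ndarray, smoothing_level: float) -> np.ndarray:
    """Nominal mm smoothing mapped to a 1-D Gaussian over the voxel index.

    Levels {0, 2, 4} mm correspond to sigma {0, 1, 2} voxels; synthetic
    voxels carry no geometry, so the label only fixes the kernel width.
    """
    if smoothing_level == 0:
        return data
    return gaussian_filter1d(data, sigma=smoothing_level / 2.0, axis=1, mode="nearest")


def clean_run(run: RoiRunData, smoothing_level: float = 0.0) -> np.ndarray:
    """Detrend, regress out motion confounds, and z-score one run per voxel."""
    if np.isnan(run.data).any():
        raise ValueError("run data contains NaNs")
    data = smooth_voxels(run.data, smoothing_level)
    with warnings.catch_warnings():
        # nilearn announces a future change in confound standardization
        # (sample vs population std), which is immaterial at these sizes
        warnings.simplefilter("ignore", DeprecationWarning)
        return nilearn_clean(
            data,
            detrend=True,
            standardize="zscore_sample",
            confounds=run.motion_confounds,
            t_r=run.tr,
        )


def _volume_index(onset: float, tr: float, mode: str = "nearest") -> int:
    return int(np.floor(onset / tr)) if mode == "floor" else int(round(onset / tr))


def _training_samples(
    runs: list[RoiRunData],
    cfg: DecodingConfig,
    lock: str,
    cleaned: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for run in runs:
        data = cleaned[run.run_id] if cleaned else clean_run(run, cfg.smoothing_level)
        ev = run.events
        if lock == "feedback":
            eligible = ev[ev["feedback"] & ev["choice_city"].notna()]
            onset_col = "feedback_onset"
        else:  # localizer response-locked samples
            eligible = ev[ev["target"].notna()] if "target" in ev else ev
            onset_col = "response_onset"
        for _, row in eligible.iterrows():
            idx = _volume_index(row[onset_col] + cfg.lag_seconds, cfg.tr)
            if 0 <= idx < len(data):
                X.append(data[idx])
                y.append(row["choice_city"] if lock == "feedback" else row["target"])
    return np.asarray(X), np.asarray(y)


def train_policy_decoder(
    runs: list[RoiRunData], cfg: DecodingConfig, cleaned: dict | None = None
) -> EvidenceDecoder:
    """Train the 4-city decoder on feedback-locked volumes of training trials.

    Only trials that showed feedback enter training; omitted trials are
    excluded; the volume is taken ``lag_seconds`` after feedback onset
    (nearest TR); classes are balanced by random subsampling.
    """
    X, y = _training_samples(runs, cfg, "feedback", cleaned)
    if len(X) == 0:
        raise ValueError("no eligible feedback trials in the training runs")
    from .task import CITIES

    missing = set(CITIES) - set(y)
    if missing:
        raise ValueError(f"no training trials for classes: {sorted(missing)}")
    model = EvidenceDecoder(
        n_subsamples=cfg.n_subsamples, C=cfg.regularization, random_state=cfg.seed
    )
    return model.fit(X, y)


def train_feature_decoder(
    localizer_runs: list[RoiRunData], cfg: DecodingConfig
) -> EvidenceDecoder:
    """Train the 12-class feature-number decoder on response-locked localizer data."""
    X, y = [], []
    for run in localizer_runs:
        data = clean_run(run, cfg.smoothing_level)
        numbers = run.events[run.events["trial_type"] == "number"]
        for _, row in numbers.iterrows():
            idx = _volume_index(row["response_onset"] + cfg.lag_seconds, cfg.tr)
            if 0 <= idx < len(data):
                X.append(data[idx])
                y.append(int(row["target"]))
    model = EvidenceDecoder(
        n_subsamples=cfg.n_subsamples, C=cfg.regularization, random_state=cfg.seed
    )
    return model.fit(np.asarray(X), np.asarray(y))


def decode_timecourse(
    model: EvidenceDecoder,
    cleaned: np.ndarray,
    events: pd.DataFrame,
    cfg: DecodingConfig,
    lock: str = "cue",
    trial_mask: pd.Series | None = None,
) -> ProbabilityTimecourse:
    """Evidence time course for each trial of one (held-out) run.

    Cue lock: TR_0 is the nearest TR to cue onset, offsets 0..+12.
    Response lock: TR_0 is the earlier TR closest to response-phase onset,
    offsets 0..+6.  Offsets falling outside the run are NaN.
    """
    if lock not in ("cue", "response"):
        raise ValueError("lock must be 'cue' or 'response'")
    offsets = np.array(CUE_OFFSETS if lock == "cue" else RESPONSE_OFFSETS)
    trials = events if trial_mask is None else events[trial_mask]
    onset_col = "onset" if lock == "cue" else "response_onset"
    mode = "nearest" if lock == "cue" else "floor"
    base = [_volume_index(o, cfg.tr, mode) for o in trials[onset_col]]
    if any(b < 0 or b >= len(cleaned) for b in base):
        raise ValueError("trial onset outside the run")
    probs = np.full((len(trials), len(offsets), len(model.classes_)), np.nan)
    flat_rows, flat_pos = [], []
    for i, b in enumerate(base):
        for j, off in enumerate(offsets):
            if 0 <= b + off < len(cleaned):
                flat_rows.append(cleaned[b + off])
                flat_pos.append((i, j))
    if flat_rows:
        ev = model.evidence(np.asarray(flat_rows))
        for (i, j), row in zip(flat_pos, ev):
            probs[i, j] = row
    return ProbabilityTimecourse(
        probs=probs,
        classes=model.classes_,
        offsets=offsets,
        trials=trials.reset_index(drop=True),
    )


def _with_prev_choice(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.sort_values("trial_index").copy()
    ev["prev_choice_city"] = ev["choice_city"].shift(1)
    if "choice_triplet" in ev:
        ev["prev_choice_triplet"] = ev["choice_triplet"].shift(1)
    return ev


def decode_test_trials(
    runs: list[RoiRunData],
    cfg: DecodingConfig,
    lock: str = "cue",
    model_builder=None,
) -> ProbabilityTimecourse:
    """Leave-one-run-out decoding of test trials across a set of runs.

    For each held-out run the decoder is trained on the feedback trials of
    all remaining runs only; by construction no held-out volume enters
    training.  Returns the concatenated test-trial time courses.
    """
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    cleaned = {run.run_id: clean_run(run, cfg.smoothing_level) for run in runs}
    builder = model_builder or train_policy_decoder
    pieces = []
    for held_out in runs:
        train_runs = [r for r in runs if r.run_id != held_out.run_id]
        try:
            model = builder(
                train_runs, cfg, cleaned={r.run_id: cleaned[r.run_id] for r in train_runs}
            )
        except ValueError as err:
            if "no training trials" not in str(err):
                raise
            # a fold whose training runs miss a class cannot be decoded;
            # skip it rather than aborting the whole leave-one-run-out loop
            warnings.warn(
                f"skipping held-out run {held_out.run_id}: {err}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        ev = _with_prev_choice(held_out.events)
        mask = ev["trial_type"] == "test"
        if not mask.any():
            continue
        ptc = decode_timecourse(model, cleaned[held_out.run_id], ev, cfg, lock, mask)
        pieces.append(ptc)
    if not pieces:
        raise ValueError("no test trials found in any run")
    return ProbabilityTimecourse(
        probs=np.concatenate([p.probs for p in pieces]),
        classes=pieces[0].classes,
        offsets=pieces[0].offsets,
        trials=pd.concat([p.trials for p in pieces], ignore_index=True),
    )


def decode_with_model(
    model: EvidenceDecoder,
    runs: list[RoiRunData],
    cfg: DecodingConfig,
    lock: str = "cue",
    trial_type: str = "test",
) -> ProbabilityTimecourse:
    """Decode one trial type across runs with an externally trained model.

    Used for feature decoding, where the 12-class model comes from the
    localizer session and is therefore independent of every run decoded here
    (no leave-one-run-out needed).
    """
    pieces = []
    for run in runs:
        ev = _with_prev_choice(run.events)
        mask = ev["trial_type"] == trial_type
        if not mask.any():
            continue
        cleaned = clean_run(run, cfg.smoothing_level)
        pieces.append(decode_timecourse(model, cleaned, ev, cfg, lock, mask))
    if not pieces:
        raise ValueError(f"no {trial_type!r} trials found in any run")
    return ProbabilityTimecourse(
        probs=np.concatenate([p.probs for p in pieces]),
        classes=pieces[0].classes,
        offsets=pieces[0].offsets,
        trials=pd.concat([p.trials for p in pieces], ignore_index=True),
    )


def categorize_evidence(
    ptc: ProbabilityTimecourse,
    block_mappings: dict,
    rm=None,
) -> CategoryEvidence:
    """Sort the four city probabilities into policy categories per test trial.

    ``block_mappings`` maps block id -> city_to_triplet bijection (the
    mapping changes across blocks).  A category's probability is excluded on
    trials where the city of that category was the one chosen on the
    previous trial, to avoid carry-over of the previous trial's signal.
    """
    rm = rm or full_reward_matrix()
    n_trials, n_off, _ = ptc.probs.shape
    evidence = np.full((n_trials, n_off, len(POLICY_CATEGORIES)), np.nan)
    excluded = np.zeros((n_trials, len(POLICY_CATEGORIES)), dtype=bool)
    for i, row in ptc.trials.iterrows():
        cats = policy_categories(row["task_id"])
        c2t = block_mappings[row["block"]]
        t2c = {t: c for c, t in c2t.items()}
        if sorted(cats.values()) != [1, 2, 3, 4]:
            raise RuntimeError("policy categories must partition the four policies")
        for k, cat in enumerate(POLICY_CATEGORIES):
            city = t2c[cats[cat]]
            evidence[i, :, k] = ptc.probs[i, :, ptc.class_index(city)]
            prev = row.get("prev_choice_city")
            if isinstance(prev, str) and prev == city:
                excluded[i, k] = True
    return CategoryEvidence(
        evidence=evidence,
        excluded=excluded,
        offsets=ptc.offsets,
        trials=ptc.trials,
    )


def window_average(
    ce: CategoryEvidence, cfg: DecodingConfig | None = None
) -> pd.Series:
    """Mean evidence per category over the analysis window and unmasked trials.

    A category whose trials are all excluded yields NaN (flagged missing, not
    silently zero).
    """
    window = cfg.window if cfg is not None else (2, 10)
    off = ce.offsets if ce.offsets is not None else np.arange(ce.evidence.shape[1])
    in_window = (off >= window[0]) & (off <= window[1])
    out = {}
    for k, cat in enumerate(ce.categories):
        keep = ~ce.excluded[:, k]
        if not keep.any():
            warnings.warn(f"all trials excluded for category {cat!r}", RuntimeWarning, stacklevel=2)
            out[cat] = np.nan
            continue
        vals = ce.evidence[keep][:, in_window, k]
        out[cat] = float(np.nanmean(vals))
    return pd.Series(out)


def timecourse_by_category(ce: CategoryEvidence) -> pd.DataFrame:
    """Mean evidence per category at each offset (exclusions applied)."""
    off = ce.offsets if ce.offsets is not None else np.arange(ce.evidence.shape[1])
    rows = {}
    for k, cat in enumerate(ce.categories):
        keep = ~ce.excluded[:, k]
        rows[cat] = np.nanmean(ce.evidence[keep, :, k], axis=0) if keep.any() else np.full(len(off), np.nan)
    return pd.DataFrame(rows, index=pd.Index(off, name="offset"))


def prioritization(window_means: pd.Series) -> pd.Series:
    """Evidence for each optimal training policy minus the objective best."""
    best = window_means["objective_best"]
    return pd.Series(
        {
            "more_minus_best": window_means["more_rewarding_training"] - best,
            "less_minus_best": window_means["less_rewarding_training"] - best,
        }
    )


def validation_grid(
    runs: list[RoiRunData],
    cfg: DecodingConfig | None = None,
    lags: tuple = (4.0, 5.0, 6.0),
    smoothings: tuple = (0.0, 2.0, 4.0),
    n_subsamples: int = 25,
    score_window: tuple[int, int] = (3, 7),
) -> dict:
    """Explore lag x smoothing on training trials; pick the best combination.

    For each combination, decoders are trained (leave-one-run-out) on
    feedback trials and scored by the mean held-out evidence for the chosen
    city over a 5 s window (3.75-8.75 s, TR offsets 3..7) after feedback
    onset.  The selection is flagged unstable when the winning margin over
    chance is within the spread of the grid scores (a noise floor).
    """
    if len(runs) < 2:
        raise ValueError("the validation grid needs at least 2 runs")
    base = cfg or DecodingConfig()
    scores = {}
    for lag in lags:
        for sm in smoothings:
            c = DecodingConfig(
                lag_seconds=lag,
                smoothing_level=sm,
                n_subsamples=n_subsamples,
                tr=base.tr,
                regularization=base.regularization,
                seed=base.seed,
            )
            cleaned = {r.run_id: clean_run(r, sm) for r in runs}
            vals = []
            for held_out in runs:
                train_runs = [r for r in runs if r.run_id != held_out.run_id]
                model = train_policy_decoder(
                    train_runs, c, cleaned={r.run_id: cleaned[r.run_id] for r in train_runs}
                )
                ev = held_out.events
                mask = ev["feedback"] & ev["choice_city"].notna()
                if not mask.any():
                    continue
                sub = ev[mask]
                data = cleaned[held_out.run_id]
                rows, trial_cls, trial_id = [], [], []
                for t, row in enumerate(sub.itertuples()):
                    b = _volume_index(row.feedback_onset, c.tr)
                    cls = int(np.flatnonzero(model.classes_ == row.choice_city)[0])
                    for o in range(score_window[0], score_window[1] + 1):
                        if 0 <= b + o < len(data):
                            rows.append(data[b + o])
                            trial_cls.append(cls)
                            trial_id.append(t)
                if not rows:
                    continue
                e = model.evidence(np.asarray(rows))
                picked = e[np.arange(len(rows)), trial_cls]
                vals.extend(
                    pd.Series(picked).groupby(np.asarray(trial_id)).mean().tolist()
                )
            scores[(lag, sm)] = float(np.mean(vals))
    table = pd.Series(scores).rename("score")
    table.index.names = ["lag_seconds", "smoothing_level"]
    best = table.idxmax()
    spread = float(table.std())
    unstable = (table.max() - 0.25) < 2.0 * spread + 1e-9
    return {
        "best_lag": float(best[0]),
        "best_smoothing": float(best[1]),
        "scores": table,
        "unstable": bool(unstable),
    }


def excluded_reward_features(rm=None) -> set:
    """Feature numbers equal to an optimal training-task reward (excluded)."""
    rm = rm or full_reward_matrix()
    rewards = {rm.reward(t, rm.best_policy(t)) for t in TRAIN_TASK_IDS}
    return {n for n in FEATURE_NUMBERS if float(n) in rewards}


def feature_evidence(
    ptc12: ProbabilityTimecourse,
    block_mappings: dict | None = None,
    rm=None,
) -> CategoryEvidence:
    """Average 12-class evidence over the features of each optimal training policy.

    Per test trial and category (more/less rewarding training policy), the
    probabilities of the three feature numbers of that policy's triplet are
    averaged, excluding numbers that equal an optimal training reward and
    numbers belonging to the triplet selected on the previous trial.  Chance
    is 1/12 per class.  A category with no admissible features on a trial is
    excluded (missing, not zero).
    """
    rm = rm or full_reward_matrix()
    reward_excluded = excluded_reward_features(rm)
    cats = ("more_rewarding_training", "less_rewarding_training")
    n_trials, n_off, _ = ptc12.probs.shape
    evidence = np.full((n_trials, n_off, len(cats)), np.nan)
    excluded = np.zeros((n_trials, len(cats)), dtype=bool)
    trials = ptc12.trials
    for i, row in trials.iterrows():
        mapping = policy_categories(row["task_id"])
        prev_feats: set = set()
        prev = row.get("prev_choice_triplet")
        if pd.notna(prev):
            prev_feats = set(PHI[int(prev) - 1])
        for k, cat in enumerate(cats):
            feats = [
                n
                for n in PHI[mapping[cat] - 1]
                if n not in reward_excluded and n not in prev_feats
            ]
            if not feats:
                excluded[i, k] = True
                continue
            cols = [ptc12.class_index(n) for n in feats]
            evidence[i, :, k] = np.nanmean(ptc12.probs[i][:, cols], axis=1)
    return CategoryEvidence(
        evidence=evidence,
        excluded=excluded,
        categories=cats,
        offsets=ptc12.offsets,
        trials=trials,
    )


def brain_behavior_correlation(evidence, behavior) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-tailed p."""
    evidence = np.asarray(evidence, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if len(evidence) != len(behavior):
        raise ValueError("evidence and behavior must cover the same participants")
    if len(evidence) < 4:
        warnings.warn("n < 4: correlation underpowered", RuntimeWarning, stacklevel=2)
    rho, p = sps.spearmanr(evidence, behavior)
    return float(rho), float(p)
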