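"""Advanced IBI quality control: random-forest bad-segment detection.

Simple outlier interpolation misses whole stretches of corrupted signal
(detached sensors, movement noise), which then turn into confidently
wrong stage labels. This module computes summary features on fixed
10-min windows, classifies each window good/bad with a tree ensemble
trained on labeled windows, expands bad windows onto the 30-s epoch
grid, imputes masked stage labels from surrounding clean epochs, and
declares a night unstageable when more than 25% of its epochs are bad.
Recording-level screening collects the four exclusion reasons (poor
quality, unreadable, too short, unsyncable).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .ibi_core import BAD, EpochGrid, Hypnogram, IBISeries

#: candidate QC feature set; permutation importance prunes it to k (default 7)
CANDIDATE_FEATURES = (
    "median_ibi",
    "iqr_ibi",
    "rmssd",
    "out_of_range_frac",
    "big_change_frac",
    "coverage_deficit",
    "lag1_autocorr",
    "max_min_ratio",
)

DEFAULT_WINDOW_S = 600.0  # fixed 10-min QC window
_IBI_RANGE_MS = (300.0, 2000.0)
_BIG_CHANGE = 0.20


@dataclass
class QCWindow:
    start_s: float
    duration_s: float
    feature_vector: dict[str, float]
    label: str = "unlabeled"  # {good, bad, unlabeled}

    def __post_init__(self):
        if self.label not in ("good", "bad", "unlabeled"):
            raise ValueError(f"unknown window label {self.label!r}")


@dataclass
class QCModel:
    """Trained bad-IBI detector: feature names, tree ensemble, threshold
    on the bad-class probability, and held-out training metrics."""

    feature_names: tuple[str, ...]
    forest: RandomForestClassifier
    decision_threshold: float = 0.5
    training_metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        # (0,1) in normal use; the closed endpoints are allowed so the
        # flag-everything / flag-nothing boundaries remain expressible
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must be in [0,1]")
        unknown = set(self.feature_names) - set(CANDIDATE_FEATURES)
        if unknown:
            raise ValueError(f"feature names outside candidate set: {unknown}")

    def save(self, path) -> Path:
        """Versioned JSON sidecar + pickled ensemble bundle."""
        path = Path(path)
        meta = {
            "format_version": 1,
            "feature_names": list(self.feature_names),
            "decision_threshold": self.decision_threshold,
            "training_metrics": self.training_metrics,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path) -> "QCModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class ScreeningResult:
    """eligible iff no exclusion reason applies."""

    reasons: tuple[str, ...]

    _VALID = ("poor_quality_gt25", "unreadable", "too_short", "unsyncable")

    def __post_init__(self):
        unknown = set(self.reasons) - set(self._VALID)
        if unknown:
            raise ValueError(f"unknown screening reasons: {unknown}")
        # canonical order i-iv
        self.reasons = tuple(r for r in self._VALID if r in self.reasons)

    @property
    def eligible(self) -> bool:
        return not self.reasons


# ---------------------------------------------------------------------------
# Window features
# ---------------------------------------------------------------------------


def _window_features(iv: np.ndarray, window_s: float) -> dict[str, float]:
    """Summary features of the intervals terminating inside one window.
    ``iv`` excludes gap-crossing intervals; their absence shows up in the
    coverage deficit."""
    if iv.size == 0:
        return {
            "median_ibi": 0.0,
            "iqr_ibi": 0.0,
            "rmssd": 0.0,
            "out_of_range_frac": 0.0,
            "big_change_frac": 0.0,
            "coverage_deficit": 1.0,
            "lag1_autocorr": 0.0,
            "max_min_ratio": 1.0,
        }
    q75, q25 = np.percentile(iv, [75, 25])
    diffs = np.diff(iv)
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
    oor = float(np.mean((iv < _IBI_RANGE_MS[0]) | (iv > _IBI_RANGE_MS[1])))
    if diffs.size:
        rel = np.abs(diffs) / iv[:-1]
        big = float(np.mean(rel > _BIG_CHANGE))
    else:
        big = 0.0
    coverage = float(np.sum(iv) / 1000.0 / window_s)
    if iv.size >= 3 and np.std(iv) > 1e-12:
        x = iv - iv.mean()
        lag1 = float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
    else:
        lag1 = 0.0
    return {
        "median_ibi": float(np.median(iv)),
        "iqr_ibi": float(q75 - q25),
        "rmssd": rmssd,
        "out_of_range_frac": oor,
        "big_change_frac": big,
        "coverage_deficit": max(0.0, 1.0 - coverage),
        "lag1_autocorr": lag1,
        "max_min_ratio": float(np.max(iv) / np.min(iv)),
    }


def extract_qc_features(
    series: IBISeries,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float | None = None,
    start_s: float | None = None,
) -> list[QCWindow]:
    """Candidate features on fixed windows tiling the recording
    (non-overlapping by default: hop = window). An interval belongs to the
    window containing its terminating beat; gap-crossing intervals are
    excluded from the statistics but depress the window's coverage."""
    hop_s = window_s if hop_s is None else hop_s
    if series.duration_s < window_s:
        raise ValueError("window longer than recording")
    t0 = series.beat_times[0] if start_s is None else start_s
    t_end = series.beat_times[-1]
    term = series.beat_times[1:]
    crossing = series.gap_crossing_mask()
    windows = []
    start = t0
    while start + window_s <= t_end + 1e-9:
        sel = (term >= start) & (term < start + window_s) & ~crossing
        windows.append(
            QCWindow(start, window_s, _window_features(series.intervals[sel], window_s))
        )
        start += hop_s
    return windows


def windows_to_frame(windows: list[QCWindow]) -> pd.DataFrame:
    df = pd.DataFrame([w.feature_vector for w in windows])
    df.insert(0, "start_s", [w.start_s for w in windows])
    df["label"] = [w.label for w in windows]
    return df


# ---------------------------------------------------------------------------
# Feature selection and training
# ---------------------------------------------------------------------------


def _labeled_xy(windows, feature_names):
    labeled = [w for w in windows if w.label in ("good", "bad")]
    X = np.array([[w.feature_vector[f] for f in feature_names] for w in labeled])
    y = np.array([1 if w.label == "bad" else 0 for w in labeled])
    return X, y


def select_features_by_permutation_importance(
    windows: list[QCWindow],
    k: int = 7,
    n_repeats: int = 20,
    seed=0,
    candidates: tuple[str, ...] = CANDIDATE_FEATURES,
) -> tuple[str, ...]:
    """Top-k features by mean decrease in held-out balanced accuracy when
    the feature's column is permuted; ties broken by candidate order."""
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    X, y = _labeled_xy(windows, candidates)
    if len(set(y)) < 2:
        raise ValueError("need both good and bad labels for selection")
    if k == len(candidates):
        return tuple(candidates)
    rng = np.random.default_rng(seed)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=0.3, stratify=y, random_state=int(rng.integers(2**31))
    )
    forest = RandomForestClassifier(
        n_estimators=200, random_state=int(rng.integers(2**31)), n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    imp = permutation_importance(
        forest,
        X_ho,
        y_ho,
        scoring="balanced_accuracy",
        n_repeats=n_repeats,
        random_state=int(rng.integers(2**31)),
    )
    order = sorted(range(len(candidates)), key=lambda i: (-imp.importances_mean[i], i))
    return tuple(candidates[i] for i in sorted(order[:k]))


def train_qc_model(
    windows: list[QCWindow],
    feature_names: tuple[str, ...] = CANDIDATE_FEATURES,
    decision_threshold: float = 0.5,
    n_estimators: int = 300,
    seed=0,
) -> QCModel:
    """Random forest on labeled windows; out-of-bag AUC and accuracy are
    reported as training metrics."""
    X, y = _labeled_xy(windows, feature_names)
    if len(set(y)) < 2:
        raise ValueError("training windows must contain both labels")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=int(np.random.default_rng(seed).integers(2**31)),
        n_jobs=1,
    )
    forest.fit(X, y)
    oob_proba = forest.oob_decision_function_[:, 1]
    metrics = {
        "oob_accuracy": float(forest.oob_score_),
        "oob_auc": float(roc_auc_score(y, oob_proba)),
        "n_windows": int(y.size),
        "bad_fraction": float(y.mean()),
    }
    return QCModel(tuple(feature_names), forest, decision_threshold, metrics)


def calibrate_threshold(model: QCModel, windows: list[QCWindow]) -> float:
    """Threshold maximizing F1 on labeled validation windows — the exposed
    form of adjusting the detector's output threshold to tolerate minor
    noise while still catching real corruption."""
    X, y = _labeled_xy(windows, model.feature_names)
    proba = model.forest.predict_proba(X)[:, 1]
    best_t, best_f1 = model.decision_threshold, -1.0
    for t in np.unique(np.round(proba, 6)):
        pred = proba >= t
        tp = float(np.sum(pred & (y == 1)))
        if tp == 0:
            continue
        f1 = 2 * tp / (pred.sum() + y.sum())
        if f1 > best_f1:
            best_f1, best_t = f1, float(t)
    return min(max(best_t, 1e-6), 1 - 1e-6)


def classify_windows(
    model: QCModel, windows: list[QCWindow]
) -> tuple[np.ndarray, np.ndarray]:
    """Bad-probability per window and the boolean flags
    (prob >= decision_threshold)."""
    for w in windows:
        missing = [f for f in model.feature_names if f not in w.feature_vector]
        if missing:
            raise ValueError(f"window at {w.start_s}s missing feature {missing[0]!r}")
    X = np.array(
        [[w.feature_vector[f] for f in model.feature_names] for w in windows]
    )
    proba = model.forest.predict_proba(X)[:, 1]
    return proba, proba >= model.decision_threshold


# ---------------------------------------------------------------------------
# Epoch masking, imputation, stageability
# ---------------------------------------------------------------------------


def mask_epochs(
    flags: np.ndarray, windows: list[QCWindow], grid: EpochGrid
) -> np.ndarray:
    """Every 30-s epoch overlapping a bad window is marked bad."""
    mask = np.zeros(grid.n_epochs, dtype=bool)
    for flag, w in zip(flags, windows):
        if flag:
            mask[grid.overlapping_epochs(w.start_s, w.start_s + w.duration_s)] = True
    return mask


def mask_epochs_voted(
    flags: np.ndarray,
    windows: list[QCWindow],
    grid: EpochGrid,
    min_vote: float = 0.5,
) -> np.ndarray:
    """Epoch mask from *overlapping* windows by majority vote.

    With hop < window every epoch is covered by several windows; marking
    it bad only when at least ``min_vote`` of its covering windows are
    flagged localizes artifact boundaries to roughly hop resolution
    instead of a whole window. Reduces to :func:`mask_epochs` when the
    windows tile the grid (one vote per epoch).
    """
    votes = np.zeros(grid.n_epochs)
    covered = np.zeros(grid.n_epochs)
    for flag, w in zip(flags, windows):
        idx = grid.overlapping_epochs(w.start_s, w.start_s + w.duration_s)
        covered[idx] += 1
        if flag:
            votes[idx] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(covered > 0, votes / np.maximum(covered, 1), 0.0)
    return frac >= min_vote


def impute_bad_epochs(h: Hypnogram, mask: np.ndarray) -> Hypnogram:
    """Replace masked epochs with the stage of the nearest clean epoch;
    equidistant ties take the preceding epoch, leading runs the first
    clean stage. Clean epochs are never changed; idempotent."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != h.n_epochs:
        raise ValueError("mask length must equal n_epochs")
    if mask.all():
        raise ValueError("all epochs bad: night is unstageable")
    clean_idx = np.flatnonzero(~mask)
    stages = h.stages.copy()
    for k in np.flatnonzero(mask):
        pos = np.searchsorted(clean_idx, k)
        before = clean_idx[pos - 1] if pos > 0 else None
        after = clean_idx[pos] if pos < clean_idx.size else None
        if before is None:
            src = after
        elif after is None:
            src = before
        else:  # tie -> preceding
            src = before if (k - before) <= (after - k) else after
        stages[k] = h.stages[src]
    return Hypnogram(stages, h.grid)


def apply_mask(h: Hypnogram, mask: np.ndarray) -> Hypnogram:
    """Stamp BAD onto masked epochs (pre-imputation view)."""
    stages = h.stages.copy()
    stages[np.asarray(mask, dtype=bool)] = BAD
    return Hypnogram(stages, h.grid)


def assess_stageability(mask: np.ndarray, grid: EpochGrid) -> tuple[str, float]:
    """Unstageable iff strictly more than 25% of epochs are bad."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != grid.n_epochs:
        raise ValueError("mask length must equal n_epochs")
    bad_fraction = float(mask.mean())
    return ("unstageable" if bad_fraction > 0.25 else "stageable"), bad_fraction


def screen_recording(
    series: IBISeries | None,
    bad_fraction: float | None = None,
    sync_ok: bool = True,
    min_duration_h: float = 4.0,
) -> ScreeningResult:
    """Recording-level eligibility: unreadable (no series), too short
    (< min_duration_h), poor quality (>25% bad epochs), unsyncable."""
    reasons = []
    if series is None:
        reasons.append("unreadable")
    elif series.duration_s < min_duration_h * 3600.0:
        reasons.append("too_short")
    if bad_fraction is not None and bad_fraction > 0.25:
        reasons.append("poor_quality_gt25")
    if not sync_ok:
        reasons.append("unsyncable")
    return ScreeningResult(tuple(reasons))


def label_windows_from_truth(
    windows: list[QCWindow],
    true_mask: np.ndarray,
    grid: EpochGrid,
    bad_overlap: float = 0.3,
) -> list[QCWindow]:
    """Label windows from a ground-truth epoch mask (the synthetic stand-in
    for manual labeling): bad iff artifact epochs cover >= ``bad_overlap``
    of the window."""
    out = []
    for w in windows:
        idx = grid.overlapping_epochs(w.start_s, w.start_s + w.duration_s)
        frac = float(true_mask[idx].mean()) if idx.size else 0.0
        label = "bad" if frac >= bad_overlap else "good"
        out.append(QCWindow(w.start_s, w.duration_s, dict(w.feature_vector), label))
    return out
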