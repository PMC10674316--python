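"""Imbalance-aware 4-class sleep staging from IBI-derived features.

Light sleep dominates the night, so a classifier fitted and selected for
raw epoch-by-epoch accuracy drifts toward the majority class and loses
wake and deep sleep. Two models are therefore available: the "accuracy
model" (uniform sample weights, checkpoint with the best validation
accuracy) and the "loss function model", which weights samples by
inverse class frequency and picks the checkpoint minimizing the
class-weighted cross-entropy on validation data.

The classifier itself is a pluggable contract; the default is a
gradient-boosted tree ensemble over per-epoch HRV features computed on a
centered context window (temporal context: information about epoch N
lives partly in its neighbours), plus age and gender covariates. Its
boosting stages double as the selection checkpoints.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from sklearn.ensemble import GradientBoostingClassifier

from .ibi_core import EpochGrid, Hypnogram, IBISeries, LIGHT, STAGES_4, segment_by_epoch
from .sync import to_uniform_rate

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

FEATURE_COLUMNS = (
    "mean_ibi",
    "sdnn",
    "rmssd",
    "pnn50",
    "lf_power",
    "hf_power",
    "lf_hf_ratio",
    "is_imputed",
    "age_z",
    "gender",
)


# ---------------------------------------------------------------------------
# Epoch features
# ---------------------------------------------------------------------------


def _band_power(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def extract_epoch_features(
    series: IBISeries,
    grid: EpochGrid,
    age: float = 45.0,
    gender: str = "M",
    context_epochs: int = 11,
    fs_hz: float = 4.0,
) -> pd.DataFrame:
    """Per-epoch HRV features over a centered context window.

    Time-domain statistics (mean IBI, SDNN, RMSSD, pNN50) pool all clean
    intervals terminating inside the context window; spectral band powers
    (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz) come from the periodogram of the
    4-Hz instantaneous-rate signal over the same span. Epochs with no own
    intervals are flagged imputed and inherit context (or night-level)
    values. Age is standardized as (age-50)/20; gender is F=0 / M=1.
    """
    if context_epochs % 2 != 1:
        raise ValueError("context window length must be odd")
    half = context_epochs // 2
    n = grid.n_epochs
    per_epoch = segment_by_epoch(series, grid)
    # strip gap-crossing intervals from the per-epoch lists
    crossing = series.gap_crossing_mask()
    if crossing.any():
        term = series.beat_times[1:]
        idx = np.floor((term - grid.lights_off_s) / grid.epoch_len_s).astype(int)
        ok = (idx >= 0) & (idx < n) & ~crossing
        iv, idx = series.intervals[ok], idx[ok]
        bounds = np.searchsorted(idx, np.arange(n + 1))
        per_epoch = [iv[bounds[k]: bounds[k + 1]] for k in range(n)]

    rate = to_uniform_rate(series, fs_hz)
    rows = np.zeros((n, len(FEATURE_COLUMNS)))
    age_z = (age - 50.0) / 20.0
    g01 = 1.0 if gender == "M" else 0.0
    night_iv = (
        np.concatenate([e for e in per_epoch if e.size])
        if any(e.size for e in per_epoch)
        else np.array([800.0])
    )
    night_mean = float(np.mean(night_iv))

    for k in range(n):
        ctx = np.concatenate(per_epoch[max(0, k - half): k + half + 1])
        imputed = 1.0 if per_epoch[k].size == 0 else 0.0
        if len(ctx) < 2:
            ctx = night_iv
            imputed = 1.0
        diffs = np.diff(ctx)
        mean_ibi = float(np.mean(ctx))
        sdnn = float(np.std(ctx, ddof=1)) if ctx.size > 1 else 0.0
        rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0
        pnn50 = float(np.mean(np.abs(diffs) > 50.0)) if diffs.size else 0.0
        # spectral content over the context span
        t_lo = grid.epoch_start(max(0, k - half))
        t_hi = grid.epoch_start(min(n - 1, k + half)) + grid.epoch_len_s
        i_lo = max(0, int(np.ceil((t_lo - rate.start_s) * fs_hz)))
        i_hi = min(rate.values.size, int(np.floor((t_hi - rate.start_s) * fs_hz)))
        seg = rate.values[i_lo:i_hi]
        if seg.size >= 16 and np.std(seg) > 1e-12:
            freqs, psd = periodogram(seg, fs=fs_hz, detrend="linear")
            lf = _band_power(freqs, psd, LF_BAND)
            hf = _band_power(freqs, psd, HF_BAND)
        else:
            lf = hf = 0.0
        rows[k] = (
            mean_ibi if not np.isnan(mean_ibi) else night_mean,
            sdnn,
            rmssd,
            pnn50,
            lf,
            hf,
            lf / (hf + 1e-9),
            imputed,
            age_z,
            g01,
        )
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# Class weights and weighted loss
# ---------------------------------------------------------------------------


@dataclass
class ClassWeights:
    """Inverse-frequency class weights normalized to mean 1."""

    w: dict[str, float]

    def __post_init__(self):
        if set(self.w) != set(STAGES_4):
            raise ValueError("weights required for all four stages")
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("weights must be positive")
        mean = float(np.mean(list(self.w.values())))
        self.w = {s: v / mean for s, v in self.w.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.w[s] for s in STAGES_4])


def compute_class_weights(stage_counts: dict[str, int]) -> ClassWeights:
    """w_c proportional to 1/frequency_c, normalized to mean 1."""
    for s in STAGES_4:
        if stage_counts.get(s, 0) <= 0:
            raise ValueError(
                f"zero count for stage {s}: pool stages or enlarge the sample"
            )
    total = sum(stage_counts[s] for s in STAGES_4)
    raw = {s: total / stage_counts[s] for s in STAGES_4}
    return ClassWeights(raw)


def weighted_cross_entropy(
    probabilities: np.ndarray, labels: np.ndarray, weights: ClassWeights
) -> float:
    """L = sum_i w_{y_i} (-ln p_{i,y_i}) / sum_i w_{y_i}; zero predicted
    probability for a true label is clipped at 1e-12 with a warning."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = np.array([STAGES_4.index(s) for s in y])
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = p[np.arange(p.shape[0]), y]
    if np.any(p_true <= 0):
        warnings.warn("zero probability for a true label; clipping at 1e-12")
        p_true = np.clip(p_true, 1e-12, None)
    w = weights.as_array()[y]
    return float(np.sum(w * (-np.log(p_true))) / np.sum(w))


# ---------------------------------------------------------------------------
# Training with checkpoint selection
# ---------------------------------------------------------------------------


@dataclass
class TrainedStager:
    """Pluggable-classifier wrapper with a checkpointed history.

    The default model is a gradient-boosted classifier; a checkpoint is
    the model truncated at a boosting stage, so both selection modes pick
    from a genuine choice set. GradientBoostingClassifier cannot predict
    at an intermediate stage directly, so prediction walks
    ``staged_predict_proba`` up to the selected checkpoint.
    """

    model: GradientBoostingClassifier
    selection_mode: str
    class_weights: ClassWeights
    selected_checkpoint: int  # number of boosting stages used
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.selection_mode not in ("accuracy", "loss"):
            raise ValueError("selection_mode must be 'accuracy' or 'loss'")

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = np.asarray(features[list(FEATURE_COLUMNS)], dtype=float)
        return _proba_at_stage(self.model, X, self.selected_checkpoint)


def _proba_at_stage(model, X, n_stages: int) -> np.ndarray:
    gen = model.staged_predict_proba(X)
    return next(itertools.islice(gen, n_stages - 1, n_stages))


def _stage_labels_to_int(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return np.array([STAGES_4.index(s) for s in arr])
    return arr.astype(int)


def train_stager(
    train_features: pd.DataFrame,
    train_labels,
    val_features: pd.DataFrame,
    val_labels,
    selection_mode: str = "loss",
    seed=0,
    n_estimators: int = 120,
    checkpoint_every: int = 10,
    learning_rate: float = 0.1,
    max_depth: int = 3,
) -> TrainedStager:
    """Fit the default classifier and select a checkpoint on the validation
    set.

    The two modes are two genuinely different models, not two readouts of
    one training run: the accuracy model trains with uniform sample
    weights and takes the checkpoint with the best validation accuracy
    (and so inherits the majority-class pull of that criterion); the loss
    model trains with inverse-frequency sample weights and takes the
    checkpoint minimizing the class-weighted cross-entropy, which bakes
    the skewed stage distribution into both fitting and selection.
    """
    if selection_mode not in ("accuracy", "loss"):
        raise ValueError("selection_mode must be 'accuracy' or 'loss'")
    y_tr = _stage_labels_to_int(train_labels)
    y_va = _stage_labels_to_int(val_labels)
    if len(set(y_tr.tolist())) < 2:
        raise ValueError("degenerate single-class training set")
    if set(y_va.tolist()) != {0, 1, 2, 3}:
        raise ValueError("validation set must contain all four stages")
    counts = {s: int(np.sum(y_tr == i)) for i, s in enumerate(STAGES_4)}
    if any(v == 0 for v in counts.values()):
        raise ValueError("training set must contain all four stages")
    weights = compute_class_weights(counts)
    w_arr = weights.as_array()
    X_tr = np.asarray(train_features[list(FEATURE_COLUMNS)], dtype=float)
    X_va = np.asarray(val_features[list(FEATURE_COLUMNS)], dtype=float)
    model = GradientBoostingClassifier(
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        max_depth=max_depth,
        random_state=int(np.random.default_rng(seed).integers(2**31)),
    )
    sample_weight = w_arr[y_tr] if selection_mode == "loss" else None
    model.fit(X_tr, y_tr, sample_weight=sample_weight)

    history = []
    for stage, proba in enumerate(model.staged_predict_proba(X_va), start=1):
        if stage % checkpoint_every and stage != n_estimators:
            continue
        acc = float(np.mean(np.argmax(proba, axis=1) == y_va))
        loss = weighted_cross_entropy(proba, y_va, weights)
        history.append(
            {"checkpoint": stage, "val_accuracy": acc, "val_weighted_loss": loss}
        )
    if selection_mode == "accuracy":
        best = max(history, key=lambda h: h["val_accuracy"])
    else:
        best = min(history, key=lambda h: h["val_weighted_loss"])
    return TrainedStager(model, selection_mode, weights, best["checkpoint"], history)


def reselect(stager: TrainedStager, selection_mode: str) -> TrainedStager:
    """Re-pick the checkpoint from the recorded history under the other
    selection mode without retraining (both 'models' of a comparison share
    one training run)."""
    if selection_mode == "accuracy":
        best = max(stager.history, key=lambda h: h["val_accuracy"])
    elif selection_mode == "loss":
        best = min(stager.history, key=lambda h: h["val_weighted_loss"])
    else:
        raise ValueError("selection_mode must be 'accuracy' or 'loss'")
    return TrainedStager(
        stager.model,
        selection_mode,
        stager.class_weights,
        best["checkpoint"],
        stager.history,
    )


def predict_hypnogram(
    stager: TrainedStager, features: pd.DataFrame, grid: EpochGrid
) -> Hypnogram:
    """One 4-class label per epoch: argmax probability, ties resolved in
    the fixed order WAKE < LIGHT < DEEP < REM."""
    proba = stager.predict_proba(features)
    if proba.shape[0] != grid.n_epochs:
        raise ValueError("feature rows must match grid epochs")
    idx = np.argmax(proba, axis=1)  # first maximum == canonical order
    stages = np.array([STAGES_4[i] for i in idx], dtype=object)
    return Hypnogram(stages, grid)


def majority_class_baseline(reference: Hypnogram) -> float:
    """Chance-level accuracy of always predicting light sleep: the LIGHT
    fraction of the reference hypnogram."""
    if reference.n_epochs == 0:
        raise ValueError("empty hypnogram")
    return float(np.mean(reference.stages == LIGHT))
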