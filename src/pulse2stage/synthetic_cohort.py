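"""Synthetic overnight cohorts with known ground truth.

Generates what the pipeline consumes in a real study: a reference
hypnogram per night, stage-dependent IBI series for a reference ECG and
two wearables, device-specific artifacts, and a known inter-device clock
lag — so that every downstream operation (sync, QC, staging, agreement)
can be validated against planted truth.

Model
-----
* Sleep architecture: first-order Markov chain over (WAKE, LIGHT, DEEP,
  REM) at 30-s resolution, built so its stationary distribution is the
  target stage mix (light-sleep strict majority).
* Beats: integrate-and-fire over an instantaneous mean-IBI signal
  ``m(t) = stage mean + very-slow wander + LF and HF sinusoids + white
  beat-to-beat jitter`` with per-night random phases/frequencies. The LF
  (0.04-0.15 Hz) and HF (0.15-0.40 Hz) amplitudes are stage-specific, so
  spectral HRV features carry stage information, as they do in vivo.
* Artifacts: missed beats (two intervals merge), extra beats (one
  interval splits), movement-noise bursts (timestamp scatter), and
  sensor detachments (beats deleted, gap recorded). A ground-truth mask
  marks every 30-s epoch whose signal was modified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ibi_core import (
    DEEP,
    EPOCH_LEN_S,
    EpochGrid,
    GapRecord,
    Hypnogram,
    IBISeries,
    LIGHT,
    REM,
    STAGES_4,
    STAGE_TO_INDEX,
    WAKE,
    write_hypnogram,
    write_ibi,
)

# ---------------------------------------------------------------------------
# Stage dynamics
# ---------------------------------------------------------------------------


@dataclass
class StageDynamics:
    """Row-stochastic 4x4 transition matrix per 30-s step, initial stage WAKE."""

    transition_matrix: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (4, 4) or np.any(P < 0):
            raise ValueError("transition_matrix must be 4x4 non-negative")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        self.transition_matrix = P

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector for eigenvalue 1, normalized to a probability vector."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


# default stage mix: WAKE 0.10 / LIGHT 0.55 / DEEP 0.15 / REM 0.20
DEFAULT_STAGE_MIX = np.array([0.10, 0.55, 0.15, 0.20])


def default_dynamics(mix=DEFAULT_STAGE_MIX, switch_prob: float = 0.12) -> StageDynamics:
    """Markov kernel ``P = (1-a) I + a 1 pi^T``: stays put with prob 1-a,
    otherwise redraws from the target mix, whose stationary distribution is
    exactly ``mix``; ``a`` sets bout lengths (a=0.12 -> mean LIGHT bout
    about 9 min)."""
    mix = np.asarray(mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or np.any(mix <= 0):
        raise ValueError("mix must be a positive probability vector")
    P = (1.0 - switch_prob) * np.eye(4) + switch_prob * np.outer(np.ones(4), mix)
    return StageDynamics(P)


def simulate_hypnogram(dyn: StageDynamics, n_epochs: int, seed) -> Hypnogram:
    """Markov-chain hypnogram starting in WAKE; deterministic per seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    P = dyn.transition_matrix
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_epochs, dtype=int)
    states[0] = STAGE_TO_INDEX[WAKE]
    u = rng.random(n_epochs)
    for k in range(1, n_epochs):
        states[k] = int(np.searchsorted(cum[states[k - 1]], u[k]))
    grid = EpochGrid(0.0, n_epochs * EPOCH_LEN_S)
    stages = np.array([STAGES_4[s] for s in states], dtype=object)
    return Hypnogram(stages, grid)


# ---------------------------------------------------------------------------
# Stage-dependent IBI generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageSignature:
    """Autonomic signature of one stage: mean IBI, slow wander amplitude,
    LF/HF oscillation amplitudes and white beat-to-beat jitter (all ms)."""

    mean_ibi_ms: float
    sdnn_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    jitter_ms: float

    def __post_init__(self):
        if self.mean_ibi_ms <= 0 or min(
            self.sdnn_ms, self.lf_amp_ms, self.hf_amp_ms, self.jitter_ms
        ) < 0:
            raise ValueError("signature parameters must be positive/non-negative")


def default_signatures() -> dict[str, StageSignature]:
    """Defaults: wake has the fastest heart rate and most low-frequency
    activity; deep sleep the slowest rate and strongest HF (vagal/RSA)
    component. DEEP hf > WAKE hf and WAKE mean IBI below every sleep stage."""
    sigs = {
        WAKE: StageSignature(850.0, 50.0, 40.0, 15.0, 25.0),
        LIGHT: StageSignature(1000.0, 40.0, 25.0, 30.0, 20.0),
        DEEP: StageSignature(1100.0, 25.0, 10.0, 45.0, 15.0),
        REM: StageSignature(950.0, 60.0, 45.0, 20.0, 25.0),
    }
    assert sigs[DEEP].hf_amp_ms > sigs[WAKE].hf_amp_ms
    assert all(sigs[WAKE].mean_ibi_ms < sigs[s].mean_ibi_ms for s in (LIGHT, DEEP, REM))
    return sigs


def simulate_ibi(
    h: Hypnogram,
    signatures: dict[str, StageSignature] | None = None,
    seed=0,
    pad_s: float = 0.0,
) -> IBISeries:
    """Integrate-and-fire beat generation over the hypnogram's night.

    Beats tile ``[lights_off - pad_s, lights_on + pad_s)``; the padding
    (pre-lights-off / post-lights-on recording overhang) uses the WAKE
    signature. Degenerate all-zero-variability signatures yield exactly
    constant intervals.
    """
    signatures = signatures or default_signatures()
    missing = [s for s in STAGES_4 if s not in signatures]
    if missing:
        raise ValueError(f"missing signatures for {missing}")
    rng = np.random.default_rng(seed)
    grid = h.grid
    t0 = grid.lights_off_s - pad_s
    t_end = grid.lights_on_s + pad_s

    f_vlf = rng.uniform(0.004, 0.01)
    f_lf = rng.uniform(0.06, 0.12)
    f_hf = rng.uniform(0.20, 0.33)
    ph = rng.uniform(0.0, 2 * np.pi, size=3)
    # oscillators are narrowband, not pure tones: the phase performs a
    # random walk (rad/sqrt(s)), as in real VLF/LF/RSA activity
    drift = np.array([0.2, 0.4, 0.6])

    mean_arr = np.array([signatures[s].mean_ibi_ms for s in STAGES_4])
    sdnn_arr = np.array([signatures[s].sdnn_ms for s in STAGES_4])
    lf_arr = np.array([signatures[s].lf_amp_ms for s in STAGES_4])
    hf_arr = np.array([signatures[s].hf_amp_ms for s in STAGES_4])
    jit_arr = np.array([signatures[s].jitter_ms for s in STAGES_4])
    stage_idx = h.as_indices()
    wake_idx = STAGE_TO_INDEX[WAKE]

    n_guess = int((t_end - t0) / 0.25)  # upper bound on beat count (>=250 ms)
    noise = rng.standard_normal(n_guess)
    ph_noise = rng.standard_normal((n_guess, 3))
    beats = []
    t = t0
    i = 0
    two_pi = 2 * np.pi
    phases = ph.copy()
    freqs = np.array([f_vlf, f_lf, f_hf])
    while t < t_end:
        beats.append(t)
        k = int((t - grid.lights_off_s) / grid.epoch_len_s)
        s = stage_idx[k] if 0 <= k < stage_idx.size else wake_idx
        ibi = (
            mean_arr[s]
            + sdnn_arr[s] * np.sin(phases[0])
            + lf_arr[s] * np.sin(phases[1])
            + hf_arr[s] * np.sin(phases[2])
            + jit_arr[s] * noise[i]
        )
        ibi = max(ibi, 250.0)
        dt = ibi / 1000.0
        phases = phases + two_pi * freqs * dt + drift * np.sqrt(dt) * ph_noise[i]
        t += dt
        i += 1
    return IBISeries.from_beat_times(np.array(beats), device_tag="SYNTHETIC")


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactModel:
    """Device failure modes. Defaults emulate overnight wearable wear:
    occasional long detachments (sensor slips off), restless movement-noise
    bursts, and rare missed/extra beat detections."""

    p_missed_beat: float = 1e-4
    p_extra_beat: float = 1e-4
    detachment_rate_per_h: float = 0.25
    detachment_dur_s: tuple[float, float] = (600.0, 1800.0)
    burst_rate_per_h: float = 0.2
    burst_dur_s: tuple[float, float] = (120.0, 600.0)
    burst_noise_ms: float = 80.0

    def __post_init__(self):
        for p in (self.p_missed_beat, self.p_extra_beat):
            if not 0.0 <= p <= 1.0:
                raise ValueError("beat artifact probabilities must be in [0,1]")


def zero_artifacts() -> ArtifactModel:
    return ArtifactModel(0.0, 0.0, 0.0, (0.0, 1.0), 0.0, (0.0, 1.0), 0.0)


def inject_artifacts(
    series: IBISeries, am: ArtifactModel, grid: EpochGrid, seed
) -> tuple[IBISeries, np.ndarray]:
    """Corrupt a clean series; returns the corrupted series and the
    ground-truth per-epoch bad mask (every epoch overlapping any artifact).

    Missed beats merge two adjacent intervals into their sum; extra beats
    split an interval at a uniform random point; bursts scatter beat
    timestamps; detachments delete all beats in their span and append a
    :class:`~pulse2stage.ibi_core.GapRecord`.
    """
    rng = np.random.default_rng(seed)
    bt = series.beat_times.copy()
    duration = bt[-1] - bt[0]
    mask = np.zeros(grid.n_epochs, dtype=bool)
    spans: list[tuple[float, float]] = []

    # --- missed beats: drop interior beats
    if am.p_missed_beat > 0 and bt.size > 2:
        drop = rng.random(bt.size - 2) < am.p_missed_beat
        drop_idx = np.where(drop)[0] + 1
        for j in drop_idx:
            spans.append((bt[j - 1], bt[j + 1]))
        bt = np.delete(bt, drop_idx)

    # --- extra beats: split intervals
    if am.p_extra_beat > 0 and bt.size > 1:
        split = np.where(rng.random(bt.size - 1) < am.p_extra_beat)[0]
        new_beats = []
        for j in split:
            u = rng.uniform(0.1, 0.9)
            tb = bt[j] + u * (bt[j + 1] - bt[j])
            new_beats.append(tb)
            spans.append((bt[j], bt[j + 1]))
        if new_beats:
            bt = np.sort(np.concatenate([bt, new_beats]))

    # --- movement-noise bursts: timestamp scatter inside the span
    n_bursts = rng.poisson(am.burst_rate_per_h * duration / 3600.0)
    for _ in range(n_bursts):
        dur = rng.uniform(*am.burst_dur_s)
        start = rng.uniform(bt[0], max(bt[0] + 1.0, bt[-1] - dur))
        sel = (bt > start) & (bt < start + dur)
        if sel.sum() >= 2:
            jitter = rng.normal(0.0, am.burst_noise_ms / 1000.0, size=int(sel.sum()))
            bt[sel] = np.sort(bt[sel] + jitter)
            # restore strict global monotonicity after the scatter
            bt = np.maximum.accumulate(bt)
            bt += np.arange(bt.size) * 1e-9  # break exact ties
            spans.append((start, start + dur))

    # --- detachments: delete beats, record explicit gaps (merged if they
    # happen to overlap, so the gap list stays non-overlapping)
    gaps = list(series.gaps)
    n_det = rng.poisson(am.detachment_rate_per_h * duration / 3600.0)
    det_spans: list[tuple[float, float]] = []
    for _ in range(n_det):
        dur = rng.uniform(*am.detachment_dur_s)
        if dur >= duration:
            raise ValueError("detachment longer than recording")
        start = rng.uniform(bt[0] + 1.0, bt[-1] - dur - 1.0)
        det_spans.append((start, start + dur))
    merged: list[list[float]] = []
    for s0, s1 in sorted(det_spans):
        if merged and s0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s1)
        else:
            merged.append([s0, s1])
    for s0, s1 in merged:
        sel = (bt >= s0) & (bt < s1)
        if sel.any():
            bt = bt[~sel]
            gaps.append(GapRecord(s0, s1, "detachment"))
            spans.append((s0, s1))

    for s0, s1 in spans:
        mask[grid.overlapping_epochs(s0, s1)] = True
    out = IBISeries.from_beat_times(bt, device_tag=series.device_tag, gaps=gaps)
    return out, mask


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class NightBundle:
    """Everything one night contributes: reference hypnogram + per-device
    IBI series with their planted truth (lag, bad-epoch mask)."""

    grid: EpochGrid
    ref_hypnogram: Hypnogram
    device_series: dict[str, IBISeries]
    true_lag_s: dict[str, float]
    true_bad_mask: dict[str, np.ndarray]


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    gender: str  # {"F", "M"}
    medication: str  # {"with", "without"}
    nights: list[NightBundle]

    def __post_init__(self):
        if not 18.0 <= self.age <= 90.0:
            raise ValueError("age must be in [18, 90]")
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be F or M")
        if self.medication not in ("with", "without"):
            raise ValueError("medication must be 'with' or 'without'")


@dataclass
class CohortConfig:
    """Study conditions for the generator. Device noise/artifact levels:
    the reference ECG is near-clean and lag-free; the chest belt (H10) and
    optical arm sensor (VS) carry a uniform random clock lag within
    ``lag_range_s`` and device-specific artifact rates."""

    n_epochs: int = 960  # 8 h in bed
    pad_s: float = 300.0  # recording overhang before/after lights
    stage_mix: tuple = tuple(DEFAULT_STAGE_MIX)
    switch_prob: float = 0.12
    lag_range_s: float = 120.0
    timestamp_noise_ms: dict = field(
        default_factory=lambda: {"ecg": 1.0, "h10": 2.0, "vs": 5.0}
    )
    devices: tuple = ("ecg", "h10", "vs")
    medication_prob: float = 0.3
    female_prob: float = 0.3
    age_range: tuple = (20.0, 76.0)
    artifact_models: dict = field(
        default_factory=lambda: {
            "ecg": ArtifactModel(
                5e-5, 5e-5, 0.02, (300.0, 900.0), 0.05, (60.0, 300.0), 60.0
            ),
            "h10": ArtifactModel(),
            "vs": ArtifactModel(
                2e-4, 2e-4, 0.3, (600.0, 1800.0), 0.25, (120.0, 600.0), 90.0
            ),
        }
    )


def _derive_device_series(
    true_series: IBISeries, lag_s: float, noise_ms: float, tag: str, rng
) -> IBISeries:
    """Shift the shared beat process onto the device clock and add
    device-specific timestamp noise."""
    bt = true_series.beat_times + lag_s
    if noise_ms > 0:
        bt = bt + rng.normal(0.0, noise_ms / 1000.0, size=bt.size)
        bt = np.sort(bt)
        bt += np.arange(bt.size) * 1e-9
    return IBISeries.from_beat_times(bt, device_tag=tag)


_TAG = {"ecg": "ECG", "h10": "H10", "vs": "VS"}


def simulate_night(
    config: CohortConfig, signatures, dynamics, seed_seq: np.random.SeedSequence
) -> NightBundle:
    seeds = seed_seq.spawn(3 + 2 * len(config.devices))
    h = simulate_hypnogram(dynamics, config.n_epochs, seeds[0])
    true_beats = simulate_ibi(h, signatures, seeds[1], pad_s=config.pad_s)
    rng = np.random.default_rng(seeds[2])
    series: dict[str, IBISeries] = {}
    lags: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    for i, dev in enumerate(config.devices):
        lag = 0.0 if dev == "ecg" else float(
            rng.uniform(-config.lag_range_s, config.lag_range_s)
        )
        dev_rng = np.random.default_rng(seeds[3 + 2 * i])
        clean = _derive_device_series(
            true_beats, lag, config.timestamp_noise_ms[dev], _TAG[dev], dev_rng
        )
        # artifacts happen on the device clock; the truth mask is expressed
        # on the reference grid, so shift the grid onto the device clock
        dev_grid = EpochGrid(
            h.grid.lights_off_s + lag, h.grid.lights_on_s + lag
        )
        corrupted, mask = inject_artifacts(
            clean, config.artifact_models[dev], dev_grid, seeds[4 + 2 * i]
        )
        series[dev] = corrupted
        lags[dev] = lag
        masks[dev] = mask
    return NightBundle(h.grid, h, series, lags, masks)


def simulate_cohort(
    n_subjects: int,
    nights_per_subject: int,
    config: CohortConfig | None = None,
    seed=0,
) -> list[SubjectRecord]:
    """Deterministic cohort: per-subject covariates plus per-night bundles
    derived from one true beat process per night."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CohortConfig()
    signatures = default_signatures()
    dynamics = default_dynamics(np.asarray(config.stage_mix), config.switch_prob)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)
    records = []
    for s, sseq in enumerate(subj_seqs):
        head = sseq.spawn(nights_per_subject + 1)
        rng = np.random.default_rng(head[0])
        age = float(rng.uniform(*config.age_range))
        gender = "F" if rng.random() < config.female_prob else "M"
        medication = "with" if rng.random() < config.medication_prob else "without"
        nights = [
            simulate_night(config, signatures, dynamics, head[1 + k])
            for k in range(nights_per_subject)
        ]
        records.append(
            SubjectRecord(f"subject_{s:03d}", age, gender, medication, nights)
        )
    return records


def write_cohort(records: list[SubjectRecord], out_dir) -> Path:
    """Cohort directory layout:
    ``subject_<id>/night_<k>/{ref_hypnogram.csv, <dev>_ibi.csv, truth.json}``."""
    out_dir = Path(out_dir)
    for rec in records:
        for k, night in enumerate(rec.nights):
            d = out_dir / rec.subject_id / f"night_{k}"
            d.mkdir(parents=True, exist_ok=True)
            write_hypnogram(night.ref_hypnogram, d / "ref_hypnogram.csv")
            for dev, series in night.device_series.items():
                write_ibi(series, d / f"{dev}_ibi.csv")
            truth = {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "gender": rec.gender,
                "medication": rec.medication,
                "lights_off_s": night.grid.lights_off_s,
                "lights_on_s": night.grid.lights_on_s,
                "true_lag_s": night.true_lag_s,
                "true_bad_mask": {
                    dev: np.flatnonzero(m).tolist()
                    for dev, m in night.true_bad_mask.items()
                },
            }
            with open(d / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
    return out_dir
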