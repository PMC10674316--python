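"""Domain types and basic operations for inter-beat-interval (IBI) recordings.

An IBI series is the single input signal of the whole pipeline: beat
timestamps (seconds from recording start) plus the interval that *ends* at
each beat (milliseconds). Hypnograms are 30-s-epoch sleep-stage sequences
on a lights-off-anchored grid; the 4-class vocabulary collapses AASM
N1/N2 into LIGHT and N3 into DEEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WAKE = "WAKE"
LIGHT = "LIGHT"
DEEP = "DEEP"
REM = "REM"
BAD = "BAD"
UNSCORED = "UNSCORED"

#: canonical 4-class order; also the argmax tie-break order in staging
STAGES_4 = (WAKE, LIGHT, DEEP, REM)
STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES_4)}

#: AASM 5-class to 4-class mapping
AASM_MAP = {"W": WAKE, "N1": LIGHT, "N2": LIGHT, "N3": DEEP, "R": REM}

_VALID_LABELS = set(STAGES_4) | {BAD, UNSCORED}

EPOCH_LEN_S = 30.0

DEVICE_TAGS = ("ECG", "H10", "VS", "SYNTHETIC")


class IBIParseError(ValueError):
    """Raised when an IBI or hypnogram file cannot be parsed."""


@dataclass(frozen=True)
class GapRecord:
    """Explicit span of missing signal (sensor detachment / unreadable)."""

    start_s: float
    end_s: float
    cause: str = "detachment"

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("GapRecord requires end_s > start_s")
        if self.cause not in ("detachment", "unreadable"):
            raise ValueError(f"unknown gap cause {self.cause!r}")


@dataclass
class IBISeries:
    """Beat-anchored interval sequence.

    ``intervals[j]`` is the interval (ms) terminating at ``beat_times[j+1]``,
    i.e. it spans beats j -> j+1; there are ``len(beat_times) - 1`` intervals.
    Intervals that span a recorded gap are kept as the raw beat-time
    difference (large but positive); consumers exclude them via
    :meth:`gap_crossing_mask`.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    device_tag: str = "SYNTHETIC"
    gaps: list[GapRecord] = field(default_factory=list)

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.device_tag not in DEVICE_TAGS:
            raise ValueError(f"device_tag must be one of {DEVICE_TAGS}")
        if self.beat_times.size and self.intervals.size != self.beat_times.size - 1:
            raise ValueError("need exactly one interval per beat pair")
        if np.any(np.diff(self.beat_times) <= 0):
            bad = int(np.argmax(np.diff(self.beat_times) <= 0)) + 1
            raise ValueError(f"beat_times not strictly increasing at index {bad}")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")
        # timestamp/interval consistency, except across explicit gaps
        if self.intervals.size:
            dt_ms = np.diff(self.beat_times) * 1000.0
            mism = np.abs(dt_ms - self.intervals) > 1.0
            mism &= ~self.gap_crossing_mask()
            if np.any(mism):
                j = int(np.argmax(mism))
                raise ValueError(
                    f"interval {j} inconsistent with beat times "
                    f"({self.intervals[j]:.1f} ms vs {dt_ms[j]:.1f} ms)"
                )
        spans = sorted((g.start_s, g.end_s) for g in self.gaps)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("gaps overlap")

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_beat_times(cls, beat_times, device_tag="SYNTHETIC", gaps=None):
        bt = np.asarray(beat_times, dtype=float)
        return cls(bt, np.diff(bt) * 1000.0, device_tag, list(gaps or []))

    @classmethod
    def from_intervals(cls, intervals_ms, start_s=0.0, device_tag="SYNTHETIC"):
        iv = np.asarray(intervals_ms, dtype=float)
        bt = start_s + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        return cls(bt, iv, device_tag)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration_s(self) -> float:
        if self.beat_times.size < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])

    def gap_crossing_mask(self) -> np.ndarray:
        """Boolean mask over intervals: True where the interval overlaps a gap."""
        mask = np.zeros(self.intervals.size, dtype=bool)
        if not self.gaps or not self.intervals.size:
            return mask
        starts = self.beat_times[:-1]
        ends = self.beat_times[1:]
        for g in self.gaps:
            mask |= (starts < g.end_s) & (ends > g.start_s)
        return mask


@dataclass(frozen=True)
class EpochGrid:
    """30-s epoch grid anchored at lights-off; epochs are half-open
    ``[lights_off + 30k, lights_off + 30(k+1))``, 0-based."""

    lights_off_s: float
    lights_on_s: float
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self):
        if not self.lights_on_s > self.lights_off_s:
            raise ValueError("lights_on_s must exceed lights_off_s")

    @property
    def n_epochs(self) -> int:
        return int(math.floor((self.lights_on_s - self.lights_off_s) / self.epoch_len_s))

    @property
    def time_in_bed_min(self) -> float:
        return self.n_epochs * self.epoch_len_s / 60.0

    def epoch_start(self, k: int) -> float:
        return self.lights_off_s + k * self.epoch_len_s

    def overlapping_epochs(self, start_s: float, end_s: float) -> np.ndarray:
        """Indices of epochs whose half-open span overlaps [start_s, end_s)."""
        if end_s <= start_s:
            return np.array([], dtype=int)
        first = int(math.floor((start_s - self.lights_off_s) / self.epoch_len_s))
        last = int(math.ceil((end_s - self.lights_off_s) / self.epoch_len_s)) - 1
        first = max(first, 0)
        last = min(last, self.n_epochs - 1)
        if last < first:
            return np.array([], dtype=int)
        return np.arange(first, last + 1)


@dataclass
class Hypnogram:
    """One stage label per grid epoch. BAD appears only after QC masking."""

    stages: np.ndarray
    grid: EpochGrid

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if self.stages.size != self.grid.n_epochs:
            raise ValueError(
                f"{self.stages.size} stages for {self.grid.n_epochs} epochs"
            )
        unknown = set(self.stages) - _VALID_LABELS
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    def as_indices(self) -> np.ndarray:
        """4-class integer codes (WAKE=0..REM=3); raises if BAD/UNSCORED present."""
        bad = [s for s in self.stages if s not in STAGE_TO_INDEX]
        if bad:
            raise ValueError(f"non-4-class labels present: {sorted(set(bad))}")
        return np.array([STAGE_TO_INDEX[s] for s in self.stages], dtype=int)

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.stages.copy(), self.grid)


# ---------------------------------------------------------------------------
# File I/O (plain delimited text, '#' header comments)
# ---------------------------------------------------------------------------


def _read_header_meta(path: Path) -> dict:
    meta: dict = {"gaps": []}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("gap:"):
                parts = body[4:].split()
                meta["gaps"].append(
                    GapRecord(float(parts[0]), float(parts[1]), parts[2])
                )
            elif ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_ibi(path, dialect: str = "beats+intervals") -> IBISeries:
    """Read an IBI file (columns ``beat_time_s[, ibi_ms]``, ``#`` comments).

    ``dialect='beats_only'`` derives intervals from consecutive beat times;
    ``'beats+intervals'`` reads both columns (the first beat's interval cell
    is empty). Non-monotone beat times are rejected naming the offending row.
    """
    path = Path(path)
    if dialect not in ("beats_only", "beats+intervals"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = _read_header_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise IBIParseError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        if "beat_time_s" in df.columns:
            return IBISeries(
                np.array([]), np.array([]),
                meta.get("device_tag", "SYNTHETIC"), meta["gaps"],
            )
        raise IBIParseError(f"{path} is empty")
    if "beat_time_s" not in df.columns:
        raise IBIParseError(f"{path}: missing beat_time_s column")
    bt = pd.to_numeric(df["beat_time_s"], errors="coerce").to_numpy()
    if np.any(np.isnan(bt)):
        row = int(np.argmax(np.isnan(bt)))
        raise IBIParseError(f"{path}: malformed beat_time_s at data row {row}")
    nonmono = np.diff(bt) <= 0
    if np.any(nonmono):
        row = int(np.argmax(nonmono)) + 1
        raise IBIParseError(f"{path}: beat times not increasing at data row {row}")
    if dialect == "beats_only" or "ibi_ms" not in df.columns:
        iv = np.diff(bt) * 1000.0
    else:
        iv_col = pd.to_numeric(df["ibi_ms"], errors="coerce").to_numpy()
        iv = iv_col[1:]
        if np.any(np.isnan(iv)):
            row = int(np.argmax(np.isnan(iv))) + 1
            raise IBIParseError(f"{path}: malformed ibi_ms at data row {row}")
    tag = meta.get("device_tag", "SYNTHETIC")
    return IBISeries(bt, iv, tag, meta["gaps"])


def write_ibi(series: IBISeries, path) -> Path:
    """Write an IBI series; lossless round trip with :func:`read_ibi`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# device_tag: {series.device_tag}\n")
        fh.write("# units: beat_time_s=s ibi_ms=ms\n")
        for g in series.gaps:
            fh.write(f"# gap: {g.start_s:.6f} {g.end_s:.6f} {g.cause}\n")
        fh.write("beat_time_s,ibi_ms\n")
        for j, t in enumerate(series.beat_times):
            iv = "" if j == 0 else f"{series.intervals[j - 1]:.6f}"
            fh.write(f"{t:.6f},{iv}\n")
    return path


def read_hypnogram(path) -> Hypnogram:
    """Read a hypnogram file (``epoch_index,onset_s,stage``).

    AASM 5-class labels (W/N1/N2/N3/R) are auto-mapped into the 4-class
    vocabulary; unknown labels raise naming the label and data row.
    """
    path = Path(path)
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise IBIParseError(f"{path}: empty hypnogram")
    stages = []
    for row, raw in enumerate(df["stage"].astype(str)):
        label = AASM_MAP.get(raw, raw)
        if label not in _VALID_LABELS:
            raise IBIParseError(f"{path}: unknown stage {raw!r} at data row {row}")
        stages.append(label)
    lights_off = float(meta.get("lights_off_s", df["onset_s"].iloc[0]))
    lights_on = float(
        meta.get("lights_on_s", df["onset_s"].iloc[-1] + EPOCH_LEN_S)
    )
    grid = EpochGrid(lights_off, lights_on)
    return Hypnogram(np.array(stages, dtype=object), grid)


def write_hypnogram(h: Hypnogram, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# lights_off_s: {h.grid.lights_off_s:.6f}\n")
        fh.write(f"# lights_on_s: {h.grid.lights_on_s:.6f}\n")
        fh.write("epoch_index,onset_s,stage\n")
        for k, s in enumerate(h.stages):
            fh.write(f"{k},{h.grid.epoch_start(k):.6f},{s}\n")
    return path


# ---------------------------------------------------------------------------
# Baseline outlier handling and epoch segmentation
# ---------------------------------------------------------------------------


def interpolate_outliers(
    series: IBISeries, min_ms: float = 300.0, max_ms: float = 2000.0
) -> tuple[IBISeries, int]:
    """Replace physiologically implausible intervals by linear interpolation.

    This is the simple outlier correction used by earlier single-channel
    models; the random-forest QC in :mod:`pulse2stage.ibi_quality` is the
    advanced alternative. Runs of consecutive outliers are interpolated
    across the run; beat times are rebuilt cumulatively from the first beat.

    Returns the corrected series and the number of replaced intervals.
    """
    if not min_ms < max_ms:
        raise ValueError("min_ms must be < max_ms")
    iv = series.intervals.copy()
    out = (iv < min_ms) | (iv > max_ms)
    n_replaced = int(out.sum())
    if n_replaced == 0:
        return series, 0
    if out.all():
        raise ValueError("no anchor for interpolation: all intervals out of range")
    idx = np.arange(iv.size)
    iv[out] = np.interp(idx[out], idx[~out], iv[~out])
    bt = series.beat_times[0] + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
    return IBISeries(bt, iv, series.device_tag, list(series.gaps)), n_replaced


def segment_by_epoch(series: IBISeries, grid: EpochGrid) -> list[np.ndarray]:
    """Per-epoch interval lists; an interval belongs to the epoch containing
    its terminating beat (half-open epochs)."""
    if series.n_beats >= 2:
        rec_start, rec_end = series.beat_times[0], series.beat_times[-1]
        if rec_end <= grid.lights_off_s or rec_start >= grid.lights_on_s:
            raise ValueError("epoch grid lies outside the recording span")
    term = series.beat_times[1:]
    idx = np.floor((term - grid.lights_off_s) / grid.epoch_len_s).astype(int)
    ok = (idx >= 0) & (idx < grid.n_epochs)
    iv, idx = series.intervals[ok], idx[ok]
    # idx is non-decreasing (beat times increase), so slice via searchsorted
    bounds = np.searchsorted(idx, np.arange(grid.n_epochs + 1))
    return [iv[bounds[k]: bounds[k + 1]] for k in range(grid.n_epochs)]
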