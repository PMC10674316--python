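"""Inter-device time alignment via windowed cross-correlation.

Wearable and reference recordings are started manually, so their clocks
carry an unknown constant offset. Both IBI series are resampled to a
uniform instantaneous-rate signal, high-pass detrended, and correlated
window by window; the global lag is the median of per-window lags with a
peak-prominence confidence and an explicit failure mode for series too
noisy to align. Clock drift is out of scope (the offset is constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .ibi_core import IBISeries


class SyncFailure(RuntimeError):
    """Raised when the two series cannot be synchronized (too noisy)."""


@dataclass
class UniformSignal:
    """Uniformly sampled signal: values[i] is at ``start_s + i / fs_hz``."""

    start_s: float
    fs_hz: float
    values: np.ndarray
    gap_mask: np.ndarray  # True where the value was held across a gap

    @property
    def end_s(self) -> float:
        return self.start_s + (self.values.size - 1) / self.fs_hz


@dataclass
class LagEstimate:
    """lag_s is signed, wearable minus reference: the device's timestamps
    run ahead of the reference clock by lag_s."""

    lag_s: float
    confidence: float
    per_window_lags: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")


def to_uniform_rate(series: IBISeries, fs_hz: float = 4.0) -> UniformSignal:
    """Instantaneous heart rate (bpm, ``60000/ibi_ms`` anchored at each
    interval's terminating beat) linearly interpolated onto a uniform grid.
    Samples inside recorded gaps hold the last value and are flagged."""
    if series.n_beats < 2:
        raise ValueError("need at least 2 beats for a rate signal")
    term = series.beat_times[1:]
    rate = 60000.0 / series.intervals
    crossing = series.gap_crossing_mask()
    # interpolation anchors: exclude gap-crossing intervals' rates
    t_anchor, r_anchor = term[~crossing], rate[~crossing]
    if t_anchor.size < 2:
        raise ValueError("not enough clean beats for a rate signal")
    n = int(np.floor((term[-1] - term[0]) * fs_hz)) + 1
    t_grid = term[0] + np.arange(n) / fs_hz
    values = np.interp(t_grid, t_anchor, r_anchor)
    gap_mask = np.zeros(n, dtype=bool)
    for g in series.gaps:
        gap_mask |= (t_grid >= g.start_s) & (t_grid < g.end_s)
    if gap_mask.any():
        # hold last pre-gap value instead of interpolating across the gap
        idx = np.where(gap_mask, 0, np.arange(n))
        idx = np.maximum.accumulate(idx)
        values = values[idx]
    return UniformSignal(float(term[0]), fs_hz, values, gap_mask)


def _highpass(values: np.ndarray, fs_hz: float, detrend_s: float) -> np.ndarray:
    """Subtract a centered moving average; removes the slow stage-level
    structure so the correlation peak is set by shared beat-level detail."""
    w = max(3, int(round(detrend_s * fs_hz)) | 1)
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(values, pad, mode="edge")
    trend = np.convolve(padded, kernel, mode="valid")
    return values - trend


def _refine_peak(curve: np.ndarray, k: int) -> float:
    """Sub-sample peak position by parabolic interpolation around index k."""
    if k <= 0 or k >= curve.size - 1:
        return float(k)
    y0, y1, y2 = curve[k - 1], curve[k], curve[k + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-15:
        return float(k)
    return k + 0.5 * (y0 - y2) / denom


def estimate_lag(
    ref_signal: UniformSignal,
    dev_signal: UniformSignal,
    window_s: float = 600.0,
    max_lag_s: float = 120.0,
    min_confidence: float = 3.0,
    detrend_s: float = 25.0,
) -> LagEstimate:
    """Windowed normalized cross-correlation between reference and device
    rate signals.

    Per window the lag is the (parabolically refined) argmax of the
    normalized cross-correlation over +-max_lag_s; the global lag is the
    median of window lags. Confidence is the ratio of the primary peak of
    the window-averaged correlation curve to the largest secondary peak
    more than 2 s away; below ``min_confidence`` a :class:`SyncFailure`
    is raised.
    """
    if abs(ref_signal.fs_hz - dev_signal.fs_hz) > 1e-9:
        raise ValueError("signals must share the sampling rate")
    fs = ref_signal.fs_hz
    win = int(round(window_s * fs))
    max_lag = int(round(max_lag_s * fs))
    if ref_signal.values.size < win or dev_signal.values.size < win:
        raise ValueError("both signals must span at least one window")
    ref_hp = _highpass(ref_signal.values, fs, detrend_s)
    dev_hp = _highpass(dev_signal.values, fs, detrend_s)
    if np.std(ref_hp) < 1e-12 or np.std(dev_hp) < 1e-12:
        raise ValueError("degenerate constant signal")

    lags_s: list[float] = []
    curves: list[np.ndarray] = []
    n_windows = ref_signal.values.size // win
    for w in range(n_windows):
        a0 = w * win
        ref_seg = ref_hp[a0: a0 + win]
        # device samples covering the window shifted by any candidate lag:
        # dev time t corresponds to ref time t - lag
        t_lo = ref_signal.start_s + a0 / fs - max_lag_s
        b0 = int(round((t_lo - dev_signal.start_s) * fs))
        b1 = b0 + win + 2 * max_lag
        if b0 < 0 or b1 > dev_signal.values.size:
            continue  # window not fully covered on the device side
        dev_seg = dev_hp[b0: b1]
        rs = ref_seg - ref_seg.mean()
        ds = dev_seg - dev_seg.mean()
        denom = np.std(rs) * np.std(ds) * win
        if denom < 1e-12:
            continue
        # curve[j] ~ corr at lag (j - max_lag)/fs
        curve = correlate(ds, rs, mode="valid", method="fft") / denom
        k = int(np.argmax(curve))
        lags_s.append((_refine_peak(curve, k) - max_lag) / fs)
        curves.append(curve)
    if not curves:
        raise ValueError("no valid correlation window (insufficient overlap)")

    mean_curve = np.mean(curves, axis=0)
    k = int(np.argmax(mean_curve))
    peak = mean_curve[k]
    excl = int(round(2.0 * fs))
    side = mean_curve.copy()
    side[max(0, k - excl): k + excl + 1] = -np.inf
    secondary = float(np.max(side)) if np.isfinite(side).any() else 0.0
    confidence = float(peak / max(secondary, 1e-12)) if peak > 0 else 0.0
    confidence = max(confidence, 0.0)
    if confidence < min_confidence:
        raise SyncFailure(
            f"confidence {confidence:.2f} below {min_confidence} "
            "(one of the two series is too noisy to align)"
        )
    return LagEstimate(float(np.median(lags_s)), confidence, lags_s)


def align(series: IBISeries, lag_s: float) -> IBISeries:
    """Shift device beat times by ``-lag_s`` onto the reference clock;
    intervals are untouched."""
    if series.duration_s and abs(lag_s) > series.duration_s:
        raise ValueError("lag exceeds recording length")
    return IBISeries(
        series.beat_times - lag_s,
        series.intervals.copy(),
        series.device_tag,
        [g.__class__(g.start_s - lag_s, g.end_s - lag_s, g.cause) for g in series.gaps],
    )
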