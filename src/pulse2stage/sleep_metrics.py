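"""Night-level sleep parameters from a 4-class hypnogram.

Six parameters per night, each from 30-s epochs (0.5 min per epoch):
sleep onset latency (SOL, lights-off to the first sleep epoch), total
sleep time (TST), sleep efficiency (SE = TST / time in bed x 100), wake
after sleep onset (WASO, all wake following the first sleep epoch up to
lights-on — no terminal-wake exclusion), and deep and REM minutes.
Hypnograms must be 4-class: BAD epochs must be imputed first.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .ibi_core import DEEP, Hypnogram, LIGHT, REM, WAKE

_SLEEP = (LIGHT, DEEP, REM)
_MIN_PER_EPOCH = 0.5


@dataclass(frozen=True)
class SleepParameters:
    sol_min: float
    se_pct: float
    tst_min: float
    waso_min: float
    rem_min: float
    deep_min: float
    no_sleep: bool = False  # all-wake night: SOL was set to time in bed

    def __post_init__(self):
        if not 0.0 <= self.se_pct <= 100.0:
            raise ValueError("SE must be within [0, 100]%")
        if min(self.sol_min, self.tst_min, self.waso_min, self.rem_min, self.deep_min) < 0:
            raise ValueError("sleep parameters must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)

    PARAMETER_NAMES = ("sol_min", "se_pct", "tst_min", "waso_min", "rem_min", "deep_min")


def _check_4class(h: Hypnogram) -> np.ndarray:
    extra = set(h.stages) - {WAKE, LIGHT, DEEP, REM}
    if extra:
        raise ValueError(
            f"hypnogram contains {sorted(extra)}; impute BAD epochs before metrics"
        )
    return h.stages


def _first_sleep_epoch(stages: np.ndarray) -> int | None:
    sleep = np.isin(stages, _SLEEP)
    return int(np.argmax(sleep)) if sleep.any() else None


def sleep_onset_latency(h: Hypnogram) -> tuple[float, bool]:
    """Minutes from lights-off to the first epoch of any sleep stage.
    All-wake nights return (time in bed, True) as a degenerate flag."""
    stages = _check_4class(h)
    k = _first_sleep_epoch(stages)
    if k is None:
        return h.grid.time_in_bed_min, True
    return k * _MIN_PER_EPOCH, False


def total_sleep_time(h: Hypnogram) -> float:
    stages = _check_4class(h)
    return float(np.isin(stages, _SLEEP).sum()) * _MIN_PER_EPOCH


def sleep_efficiency(h: Hypnogram) -> float:
    """TST / time-in-bed x 100."""
    return total_sleep_time(h) / h.grid.time_in_bed_min * 100.0


def wake_after_sleep_onset(h: Hypnogram) -> float:
    """Wake minutes strictly after the first sleep epoch, up to lights-on."""
    stages = _check_4class(h)
    k = _first_sleep_epoch(stages)
    if k is None:
        return 0.0
    return float(np.sum(stages[k + 1:] == WAKE)) * _MIN_PER_EPOCH


def stage_minutes(h: Hypnogram, stage: str) -> float:
    stages = _check_4class(h)
    if stage not in (WAKE, LIGHT, DEEP, REM):
        raise ValueError(f"unknown stage {stage!r}")
    return float(np.sum(stages == stage)) * _MIN_PER_EPOCH


def sleep_parameters(h: Hypnogram) -> SleepParameters:
    """All six parameters for one night."""
    sol, flag = sleep_onset_latency(h)
    return SleepParameters(
        sol_min=sol,
        se_pct=sleep_efficiency(h),
        tst_min=total_sleep_time(h),
        waso_min=wake_after_sleep_onset(h),
        rem_min=stage_minutes(h, REM),
        deep_min=stage_minutes(h, DEEP),
        no_sleep=flag,
    )
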