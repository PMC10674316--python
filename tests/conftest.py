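import numpy as np
import pytest

from pulse2stage.cli_pipeline import RunConfig
from pulse2stage.ibi_core import EpochGrid, Hypnogram, IBISeries
from pulse2stage.synthetic_cohort import default_signatures, simulate_hypnogram, \
    default_dynamics, simulate_ibi


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def uniform_series():
    """601 beats at exactly 1000 ms covering 600 s."""
    return IBISeries.from_beat_times(np.arange(601, dtype=float))


@pytest.fixture(scope="session")
def sim_night():
    """One default synthetic night (2 h) with its hypnogram."""
    dyn = default_dynamics()
    h = simulate_hypnogram(dyn, 240, seed=42)
    series = simulate_ibi(h, default_signatures(), seed=43, pad_s=300.0)
    return h, series


def small_run_config(seed: int = 11) -> RunConfig:
    """Down-scaled study for pipeline tests: 3-h nights, tiny cohorts,
    short boosting schedule."""
    cfg = RunConfig(
        seed=seed,
        n_subjects=2,
        nights_per_subject=1,
        n_epochs=360,
        n_train_subjects=3,
        n_estimators=40,
        checkpoint_every=10,
        min_duration_h=1.0,
    )
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_run_config()


def make_hypnogram(stages) -> Hypnogram:
    grid = EpochGrid(0.0, len(stages) * 30.0)
    return Hypnogram(np.array(stages, dtype=object), grid)
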