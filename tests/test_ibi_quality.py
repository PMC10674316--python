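import numpy as np
import pytest

from pulse2stage.ibi_core import BAD, DEEP, EpochGrid, GapRecord, IBISeries, LIGHT, \
    REM, WAKE
from pulse2stage.ibi_quality import (
    CANDIDATE_FEATURES,
    QCWindow,
    ScreeningResult,
    assess_stageability,
    classify_windows,
    extract_qc_features,
    impute_bad_epochs,
    apply_mask,
    label_windows_from_truth,
    mask_epochs,
    mask_epochs_voted,
    screen_recording,
    select_features_by_permutation_importance,
    train_qc_model,
)
from .conftest import make_hypnogram


def synthetic_windows(rng, n=200, separation=3.0):
    """Labeled windows where coverage_deficit and out_of_range_frac carry
    the signal and everything else is noise."""
    out = []
    for i in range(n):
        bad = i % 2 == 1
        feats = {f: float(rng.normal()) for f in CANDIDATE_FEATURES}
        feats["coverage_deficit"] = float(
            np.clip(rng.normal(0.45 if bad else 0.02, 0.45 / separation), 0, 1)
        )
        feats["out_of_range_frac"] = float(
            np.clip(rng.normal(0.2 if bad else 0.0, 0.2 / separation), 0, 1)
        )
        out.append(QCWindow(600.0 * i, 600.0, feats, "bad" if bad else "good"))
    return out


class TestExtractFeatures:
    def test_constant_beats_degenerate(self, uniform_series):
        w = extract_qc_features(uniform_series)[0]
        f = w.feature_vector
        assert f["iqr_ibi"] == 0.0 and f["rmssd"] == 0.0
        assert f["out_of_range_frac"] == 0.0
        assert abs(f["coverage_deficit"]) < 0.01
        assert f["median_ibi"] == 1000.0 and f["max_min_ratio"] == 1.0

    def test_gap_halves_coverage(self):
        bt = np.concatenate([np.arange(0.0, 150.0), np.arange(450.0, 601.0)])
        s = IBISeries.from_beat_times(bt, gaps=[GapRecord(149.5, 449.5)])
        w = extract_qc_features(s, 600.0)[0]
        assert abs(w.feature_vector["coverage_deficit"] - 0.5) < 0.01

    def test_rmssd_alternating_closed_form(self):
        iv = np.tile([600.0, 1400.0], 300)
        s = IBISeries.from_intervals(iv)
        w = extract_qc_features(s, 600.0)[0]
        assert abs(w.feature_vector["rmssd"] - 800.0) < 1e-9

    def test_window_longer_than_recording(self, uniform_series):
        with pytest.raises(ValueError, match="window longer"):
            extract_qc_features(uniform_series, 1200.0)


class TestFeatureSelection:
    def test_planted_signal_outranks_noise(self, rng):
        windows = synthetic_windows(rng)
        top = select_features_by_permutation_importance(windows, k=2, seed=0)
        assert "coverage_deficit" in top

    def test_k_equal_all_is_identity(self, rng):
        windows = synthetic_windows(rng, n=60)
        top = select_features_by_permutation_importance(
            windows, k=len(CANDIDATE_FEATURES), seed=0
        )
        assert top == CANDIDATE_FEATURES

    def test_deterministic(self, rng):
        windows = synthetic_windows(rng)
        a = select_features_by_permutation_importance(windows, k=7, seed=4)
        b = select_features_by_permutation_importance(windows, k=7, seed=4)
        assert a == b

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            select_features_by_permutation_importance(
                synthetic_windows(rng, n=20), k=9
            )


class TestTrainAndClassify:
    def test_separable_high_auc(self, rng):
        model = train_qc_model(synthetic_windows(rng), seed=0)
        assert model.training_metrics["oob_auc"] >= 0.9

    def test_single_class_rejected(self, rng):
        windows = [w for w in synthetic_windows(rng, n=40) if w.label == "good"]
        with pytest.raises(ValueError, match="both labels"):
            train_qc_model(windows, seed=0)

    def test_threshold_monotonicity_and_boundaries(self, rng):
        windows = synthetic_windows(rng)
        model = train_qc_model(windows, seed=0)
        counts = []
        for t in (0.0, 0.25, 0.5, 0.75):
            model.decision_threshold = t
            _, flags = classify_windows(model, windows)
            counts.append(flags.sum())
        assert counts[0] == len(windows)  # threshold 0 flags everything
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_feature_named(self, rng):
        windows = synthetic_windows(rng, n=40)
        model = train_qc_model(windows, seed=0)
        broken = QCWindow(0.0, 600.0, {"median_ibi": 1.0})
        with pytest.raises(ValueError, match="iqr_ibi"):
            classify_windows(model, [broken])


class TestMasking:
    def _tiling(self, n, flags):
        windows = [QCWindow(600.0 * i, 600.0, {}) for i in range(n)]
        return windows, np.array(flags, dtype=bool)

    def test_one_bad_window_masks_twenty_epochs(self):
        grid = EpochGrid(0.0, 1200.0)
        windows, flags = self._tiling(2, [True, False])
        mask = mask_epochs(flags, windows, grid)
        assert mask.sum() == 20 and mask[:20].all()

    def test_no_bad_windows(self):
        grid = EpochGrid(0.0, 1200.0)
        windows, flags = self._tiling(2, [False, False])
        assert not mask_epochs(flags, windows, grid).any()

    def test_truncated_epoch_at_night_end_masked(self):
        grid = EpochGrid(0.0, 630.0)  # 21 epochs
        windows, flags = self._tiling(2, [False, True])
        mask = mask_epochs(flags, windows, grid)
        assert mask.tolist() == [False] * 20 + [True]

    def test_voted_reduces_to_tiling_mask(self, rng):
        grid = EpochGrid(0.0, 6000.0)
        windows, _ = self._tiling(10, [False] * 10)
        flags = rng.random(10) < 0.4
        assert np.array_equal(
            mask_epochs_voted(flags, windows, grid, min_vote=0.5),
            mask_epochs(flags, windows, grid),
        )


class TestImputation:
    @pytest.mark.parametrize(
        "stages,mask,expected",
        [
            ([LIGHT, BAD, LIGHT], [0, 1, 0], [LIGHT, LIGHT, LIGHT]),
            ([WAKE, BAD, DEEP], [0, 1, 0], [WAKE, WAKE, DEEP]),  # tie -> preceding
            ([BAD, BAD, REM], [1, 1, 0], [REM, REM, REM]),  # leading run
            ([WAKE, BAD, BAD, BAD, DEEP], [0, 1, 1, 1, 0],
             [WAKE, WAKE, WAKE, DEEP, DEEP]),
        ],
    )
    def test_nearest_clean_rules(self, stages, mask, expected):
        h = make_hypnogram(stages)
        out = impute_bad_epochs(h, np.array(mask, dtype=bool))
        assert list(out.stages) == expected

    def test_clean_untouched_and_idempotent(self, rng):
        stages = rng.choice([WAKE, LIGHT, DEEP, REM], size=60)
        h = make_hypnogram(list(stages))
        mask = rng.random(60) < 0.3
        out = impute_bad_epochs(h, mask)
        assert np.array_equal(out.stages[~mask], h.stages[~mask])
        again = impute_bad_epochs(out, mask)
        assert np.array_equal(again.stages, out.stages)

    def test_all_bad_rejected(self):
        h = make_hypnogram([LIGHT, LIGHT])
        with pytest.raises(ValueError, match="unstageable"):
            impute_bad_epochs(h, np.array([True, True]))

    def test_apply_mask_stamps_bad(self):
        h = make_hypnogram([LIGHT, LIGHT, REM])
        out = apply_mask(h, np.array([False, True, False]))
        assert list(out.stages) == [LIGHT, BAD, REM]


class TestStageability:
    def test_boundary_strictly_greater_than_quarter(self):
        grid = EpochGrid(0.0, 100 * 30.0)
        mask = np.zeros(100, dtype=bool)
        mask[:25] = True
        assert assess_stageability(mask, grid) == ("stageable", 0.25)
        mask[25] = True
        verdict, frac = assess_stageability(mask, grid)
        assert verdict == "unstageable" and frac == 0.26

    def test_permutation_invariant(self, rng):
        grid = EpochGrid(0.0, 80 * 30.0)
        mask = rng.random(80) < 0.3
        v1, f1 = assess_stageability(mask, grid)
        perm = rng.permutation(mask)
        v2, f2 = assess_stageability(perm, grid)
        assert (v1, f1) == (v2, f2)


class TestScreening:
    def test_clean_full_night_eligible(self):
        s = IBISeries.from_intervals(np.full(5 * 3600, 1000.0))
        assert screen_recording(s, bad_fraction=0.05).eligible

    def test_short_recording(self):
        s = IBISeries.from_intervals(np.full(3 * 3600, 1000.0))
        assert screen_recording(s).reasons == ("too_short",)

    def test_poor_quality(self):
        s = IBISeries.from_intervals(np.full(5 * 3600, 1000.0))
        assert screen_recording(s, bad_fraction=0.30).reasons == ("poor_quality_gt25",)

    def test_unreadable_and_unsyncable(self):
        r = screen_recording(None, sync_ok=False)
        assert not r.eligible
        assert set(r.reasons) == {"unreadable", "unsyncable"}

    def test_eligible_iff_no_reasons(self):
        assert ScreeningResult(()).eligible
        assert not ScreeningResult(("too_short",)).eligible


def test_label_windows_from_truth_overlap_rule():
    grid = EpochGrid(0.0, 1200.0)
    truth = np.zeros(40, dtype=bool)
    truth[:8] = True  # 8 of the 20 epochs of window 0 -> 40% coverage
    windows = [QCWindow(0.0, 600.0, {}), QCWindow(600.0, 600.0, {})]
    labeled = label_windows_from_truth(windows, truth, grid, bad_overlap=0.3)
    assert [w.label for w in labeled] == ["bad", "good"]
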