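import numpy as np
import pytest
from scipy import stats

from pulse2stage.agreement import (
    agreement_report,
    bland_altman,
    cohens_kappa,
    confusion_and_rates,
    icc_agreement,
    icc_category,
    kappa_from_labels,
    mdc,
    rank_sum_test,
    sme,
    spearman_rho,
    wilcoxon_signed_rank,
)
from pulse2stage.ibi_core import DEEP, LIGHT, REM, WAKE
from pulse2stage.sleep_metrics import SleepParameters, sleep_parameters
from .conftest import make_hypnogram


class TestConfusion:
    def test_identical_hypnograms(self):
        h = make_hypnogram([WAKE, LIGHT, DEEP, REM] * 5)
        rep = confusion_and_rates(h, h)
        assert rep.accuracy == 1.0 and rep.kappa == 1.0
        assert all(m["f1"] == 1.0 for m in rep.per_class.values())

    def test_orientation_rows_predicted(self):
        pred = make_hypnogram([WAKE, WAKE])
        ref = make_hypnogram([WAKE, LIGHT])
        rep = confusion_and_rates(pred, ref)
        assert rep.confusion[0, 1] == 1  # predicted WAKE, truly LIGHT

    def test_precision_recall_f1_arithmetic(self):
        # WAKE: TP=45, FP=5, FN=10 among 200 epochs
        pred = [WAKE] * 45 + [WAKE] * 5 + [LIGHT] * 10 + [LIGHT] * 140
        ref = [WAKE] * 45 + [LIGHT] * 5 + [WAKE] * 10 + [LIGHT] * 140
        rep = confusion_and_rates(make_hypnogram(pred), make_hypnogram(ref))
        m = rep.per_class[WAKE]
        assert abs(m["precision"] - 0.9) < 1e-12
        assert abs(m["recall"] - 45 / 55) < 1e-12
        assert abs(m["f1"] - 2 * 0.9 * (45 / 55) / (0.9 + 45 / 55)) < 1e-12

    def test_empty_class_flagged_f1_zero(self):
        pred = make_hypnogram([LIGHT, LIGHT])
        ref = make_hypnogram([LIGHT, LIGHT])
        rep = confusion_and_rates(pred, ref)
        assert REM in rep.empty_classes
        assert rep.per_class[REM]["f1"] == 0.0


class TestKappa:
    def test_worked_2x2(self):
        assert abs(cohens_kappa(np.array([[40, 10], [5, 45]])) - 0.70) < 1e-12

    def test_chance_level_zero(self):
        # predict one class against a 50/50 truth
        conf = np.array([[50, 50], [0, 0]])
        assert abs(cohens_kappa(conf)) < 1e-12

    def test_single_class_undefined(self):
        assert cohens_kappa(np.array([[7, 0], [0, 0]])) is None

    def test_matches_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score
        y1 = rng.integers(0, 4, size=300)
        y2 = rng.integers(0, 4, size=300)
        conf = np.zeros((4, 4))
        np.add.at(conf, (y1, y2), 1)
        assert abs(cohens_kappa(conf) - cohen_kappa_score(y1, y2)) < 1e-12

    def test_confusion_equals_labels_route(self, rng):
        stages = np.array([WAKE, LIGHT, DEEP, REM], dtype=object)
        a = list(rng.choice(stages, 100))
        b = list(rng.choice(stages, 100))
        rep = confusion_and_rates(make_hypnogram(a), make_hypnogram(b))
        assert abs(rep.kappa - kappa_from_labels(a, b)) < 1e-12


class TestRankStatistics:
    def test_spearman_examples(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert abs(spearman_rho([1, 2, 3], [3, 1, 2]) + 0.5) < 1e-12
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == -1.0

    def test_wilcoxon_exact_five_concordant(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1],
                                   alternative="greater")
        assert res["method"] == "exact"
        assert abs(res["p"] - 1 / 32) < 1e-12

    def test_wilcoxon_degenerate_all_zero(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res["degenerate"]

    def test_wilcoxon_two_sided_doubles_one_sided(self):
        a = [2, 3, 4, 5, 6, 7]
        b = [1, 1, 1, 1, 1, 1]
        one = wilcoxon_signed_rank(a, b, "greater")["p"]
        two = wilcoxon_signed_rank(a, b, "two_sided")["p"]
        assert abs(two - 2 * one) < 1e-12

    def test_wilcoxon_exact_close_to_normal_approx(self, rng):
        d = rng.normal(0.4, 1.0, size=20)
        a, b = d, np.zeros(20)
        exact = wilcoxon_signed_rank(a, b, "greater")
        assert exact["method"] == "exact"
        approx = stats.wilcoxon(d, alternative="greater", method="approx",
                                correction=False)
        assert abs(exact["p"] - approx.pvalue) < 0.02

    def test_rank_sum_fully_separated(self):
        res = rank_sum_test([10, 11, 12, 13], [1, 2, 3, 4], alternative="greater")
        assert abs(res["p"] - 1 / 70) < 1e-12

    def test_rank_sum_identical_groups(self):
        res = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p"] > 0.9

    def test_rank_sum_statistic_symmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12)
        u1 = rank_sum_test(a, b)["statistic"]
        u2 = rank_sum_test(b, a)["statistic"]
        assert abs(u1 + u2 - 10 * 12) < 1e-9  # U1 + U2 = n_a * n_b


class TestBlandAltman:
    def test_worked_example(self):
        ba = bland_altman([0, 3, 6], [1, 2, 3])  # d = (-1, 1, 3)
        assert ba["bias"] == 1.0 and ba["sd_diff"] == 2.0
        assert abs(ba["loa_lower"] + 2.92) < 1e-12
        assert abs(ba["loa_upper"] - 4.92) < 1e-12

    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba["bias"] == 0.0 and ba["loa_lower"] == ba["loa_upper"] == 0.0

    def test_antisymmetric(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        f, r = bland_altman(x, y), bland_altman(y, x)
        assert abs(f["bias"] + r["bias"]) < 1e-12
        assert abs(f["loa_upper"] + r["loa_lower"]) < 1e-12


class TestSMEandMDC:
    def test_sme_formula(self):
        assert abs(sme([-1, 1, 3]) - 2 / np.sqrt(3)) < 1e-12
        assert sme([2.0, 2.0, 2.0]) == 0.0

    def test_sme_scaling_with_n(self, rng):
        d = rng.normal(size=50)
        d4 = np.tile(d, 4)
        # same SD, 4x the n -> SME halves (up to the tiny ddof effect)
        assert abs(sme(d4) - sme(d) / 2) < 0.01 * sme(d)

    def test_mdc_is_sme_times_196_times_sqrt2(self):
        assert round(mdc(1.8), 1) == 5.0
        assert round(mdc(1.3), 1) == 3.6
        assert round(mdc(2.2), 1) == 6.1
        assert round(mdc(0.3), 1) == 0.8
        assert mdc(0.0) == 0.0


class TestICC:
    def test_identical_columns_excellent(self):
        icc, cat = icc_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert icc == 1.0 and cat == "excellent"

    def test_worked_anova_example(self):
        icc, cat = icc_agreement([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert abs(icc - 2 / 3) < 1e-12 and cat == "moderate"

    def test_matches_pingouin_oracle(self, rng):
        import pandas as pd
        import pingouin as pg
        dev = rng.normal(10, 3, size=25)
        ref = dev + rng.normal(0.5, 1.0, size=25)
        icc, _ = icc_agreement(dev, ref)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(25), 2),
            "raters": ["dev", "ref"] * 25,
            "ratings": np.column_stack([dev, ref]).ravel(),
        })
        table = pg.intraclass_corr(long, "targets", "raters", "ratings")
        sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
        oracle = float(table.loc[sel, "ICC"].iloc[0])
        assert abs(icc - oracle) < 1e-9

    def test_koo_li_category_boundaries(self):
        assert icc_category(0.49) == "poor"
        assert icc_category(0.5) == "moderate"
        assert icc_category(0.75) == "good"
        assert icc_category(0.9) == "good"
        assert icc_category(0.91) == "excellent"

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="3"):
            icc_agreement([1.0, 2.0], [1.0, 2.0])


class TestAgreementReport:
    def _params(self, rng, jitter):
        stages = list(rng.choice([WAKE, LIGHT, DEEP, REM], size=240,
                                 p=[0.1, 0.55, 0.15, 0.2]))
        ref = sleep_parameters(make_hypnogram(stages))
        dev = SleepParameters(
            max(ref.sol_min + jitter, 0.0), ref.se_pct, ref.tst_min,
            ref.waso_min, ref.rem_min, max(ref.deep_min + jitter, 0.0),
        )
        return dev, ref

    def test_six_rows_and_perfect_pipeline(self, rng):
        pairs = [self._params(rng, 0.0) for _ in range(8)]
        table, _ = agreement_report(pairs)
        assert len(table) == 6
        assert np.allclose(table["bias"], 0.0)
        assert np.allclose(table["icc"], 1.0)

    def test_mdc_self_consistent_with_sme(self, rng):
        pairs = [self._params(rng, float(rng.normal(0, 3))) for _ in range(12)]
        table, _ = agreement_report(pairs)
        assert np.allclose(table["mdc"], table["sme"] * 1.96 * np.sqrt(2))

    def test_epoch_report_pooled(self, rng):
        h1 = make_hypnogram(list(rng.choice([WAKE, LIGHT, DEEP, REM], size=100)))
        pairs = [self._params(rng, 0.0) for _ in range(4)]
        table, rep = agreement_report(pairs, [(h1, h1)])
        assert rep.accuracy == 1.0 and rep.n_epochs == 100
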