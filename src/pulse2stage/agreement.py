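"""Device-vs-reference agreement battery.

Epoch level: confusion matrix (rows = predicted, columns = true),
accuracy, Cohen's kappa, per-class precision/recall/F1. Night level, per
sleep parameter: Bland-Altman bias and limits of agreement, standard
measurement error (SME), minimal detectable change (MDC), two-way
absolute-agreement intraclass correlation ICC(A,1) with the Koo-Li
reliability category, and Spearman's rho. Differences are oriented
device minus reference throughout, so a positive bias is a device
overestimate. Paired and unpaired non-parametric tests (Wilcoxon
signed-rank, Mann-Whitney rank-sum) round out the battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ibi_core import Hypnogram, STAGES_4, STAGE_TO_INDEX
from .sleep_metrics import SleepParameters

@dataclass
class ClassificationReport:
    """4x4 epoch-level agreement; confusion[i, j] counts epochs predicted
    as class i whose true class is j."""

    confusion: np.ndarray
    accuracy: float
    kappa: float | None
    per_class: dict[str, dict[str, float]]
    n_epochs: int
    empty_classes: tuple[str, ...] = ()

    def __post_init__(self):
        if int(self.confusion.sum()) != self.n_epochs:
            raise ValueError("confusion counts must sum to n_epochs")


@dataclass(frozen=True)
class AgreementStats:
    parameter: str
    bias: float
    loa_lower: float
    loa_upper: float
    sme: float
    mdc: float
    icc: float
    icc_category: str
    spearman_rho: float
    n: int

    def __post_init__(self):
        if self.loa_upper < self.loa_lower or self.mdc < 0 or self.icc > 1:
            raise ValueError("inconsistent agreement statistics")


# ---------------------------------------------------------------------------
# Epoch-level metrics
# ---------------------------------------------------------------------------


def confusion_and_rates(pred: Hypnogram, ref: Hypnogram) -> ClassificationReport:
    """Confusion counts plus accuracy and per-class precision/recall/F1.

    F1 = 2PR/(P+R), defined as 0 when P + R = 0; classes absent from both
    hypnograms are reported in ``empty_classes``.
    """
    if pred.n_epochs != ref.n_epochs:
        raise ValueError("hypnograms must have equal length")
    yp, yt = pred.as_indices(), ref.as_indices()
    conf = np.zeros((4, 4), dtype=int)
    np.add.at(conf, (yp, yt), 1)
    return report_from_confusion(conf)


def report_from_confusion(conf: np.ndarray) -> ClassificationReport:
    conf = np.asarray(conf, dtype=int)
    n = int(conf.sum())
    acc = float(np.trace(conf) / n) if n else 0.0
    per_class = {}
    empty = []
    for i, s in enumerate(STAGES_4):
        tp = conf[i, i]
        p_den = conf[i, :].sum()  # predicted as s
        r_den = conf[:, i].sum()  # truly s
        precision = float(tp / p_den) if p_den else 0.0
        recall = float(tp / r_den) if r_den else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[s] = {"precision": precision, "recall": recall, "f1": f1}
        if p_den == 0 and r_den == 0:
            empty.append(s)
    return ClassificationReport(
        conf, acc, cohens_kappa(conf), per_class, n, tuple(empty)
    )


def cohens_kappa(confusion: np.ndarray) -> float | None:
    """Chance-corrected agreement from a square confusion matrix:
    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals.
    Returns None when p_e = 1 (a single class on both margins)."""
    conf = np.asarray(confusion, dtype=float)
    n = conf.sum()
    if n == 0:
        return None
    p_o = np.trace(conf) / n
    p_e = float(np.dot(conf.sum(axis=1), conf.sum(axis=0)) / n**2)
    if abs(1.0 - p_e) < 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_from_labels(pred, ref) -> float | None:
    yp = np.array([STAGE_TO_INDEX[s] for s in pred])
    yt = np.array([STAGE_TO_INDEX[s] for s in ref])
    conf = np.zeros((4, 4))
    np.add.at(conf, (yp, yt), 1)
    return cohens_kappa(conf)


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rank-order correlation (average ranks for ties)."""
    res = stats.spearmanr(x, y)
    return float(res.statistic)


def wilcoxon_signed_rank(a, b, alternative: str = "two_sided") -> dict:
    """Paired signed-rank test on a - b; zero differences are dropped.

    Exact null enumeration for n <= 25 without ties, normal approximation
    with tie correction otherwise. All-zero differences are degenerate and
    flagged rather than tested.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return {"statistic": np.nan, "p": np.nan, "degenerate": True, "n": 0}
    alt = {"two_sided": "two-sided", "greater": "greater"}[alternative]
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alt, method=method, correction=False)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "degenerate": False,
        "n": int(d.size),
        "method": method,
    }


def rank_sum_test(group_a, group_b, alternative: str = "two_sided") -> dict:
    """Mann-Whitney rank-sum test for two independent groups (exact for
    small tie-free samples, tie-corrected normal approximation otherwise)."""
    a, b = np.asarray(group_a, dtype=float), np.asarray(group_b, dtype=float)
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = stats.mannwhitneyu(a, b, alternative=alt, method="auto")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n_a": int(a.size), "n_b": int(b.size)}


# ---------------------------------------------------------------------------
# Bland-Altman / SME / MDC / ICC
# ---------------------------------------------------------------------------


def bland_altman(device_values, reference_values) -> dict:
    """Bias, SD of differences, 95% limits of agreement, and their 95% CIs.

    Differences are device - reference (positive bias = device
    overestimates). LOA = bias +- 1.96 SD; CIs use the standard
    Bland-Altman variance approximations.
    """
    d = np.asarray(device_values, dtype=float) - np.asarray(reference_values, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired values")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    t = stats.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2 * (n - 1)))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_lower": float(loa_lo),
        "loa_upper": float(loa_hi),
        "bias_ci": (float(bias - t * se_bias), float(bias + t * se_bias)),
        "loa_lower_ci": (float(loa_lo - t * se_loa), float(loa_lo + t * se_loa)),
        "loa_upper_ci": (float(loa_hi - t * se_loa), float(loa_hi + t * se_loa)),
        "n": int(n),
    }


def sme(differences) -> float:
    """Standard measurement error of the paired comparison: the standard
    error of the mean difference, SD(differences)/sqrt(n)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    return float(np.std(d, ddof=1) / np.sqrt(d.size))


def mdc(sme_value: float) -> float:
    """Minimal detectable change: MDC = SME x 1.96 x sqrt(2) — the smallest
    change exceeding measurement error at 95% confidence for a
    test-retest difference."""
    if sme_value < 0:
        raise ValueError("SME must be non-negative")
    return float(sme_value * 1.96 * np.sqrt(2.0))


def icc_category(icc: float) -> str:
    """Koo-Li reliability bands: <0.5 poor, 0.5-0.75 moderate,
    0.75-0.9 good, >0.9 excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc_agreement(device_values, reference_values) -> tuple[float, str]:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
    with k = 2 raters (device, reference) from the two-way ANOVA
    decomposition over n subjects.
    """
    x = np.column_stack([
        np.asarray(device_values, dtype=float),
        np.asarray(reference_values, dtype=float),
    ])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 paired nights")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if abs(denom) < 1e-15:
        if np.allclose(x[:, 0], x[:, 1]):
            return 1.0, "excellent"  # identical raters, zero variance
        raise ValueError("degenerate data: zero total variance")
    icc = min(float((ms_r - ms_e) / denom), 1.0)  # guard float round-off
    return icc, icc_category(icc)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def agreement_report(
    parameter_pairs: list[tuple[SleepParameters, SleepParameters]],
    hypnogram_pairs: list[tuple[Hypnogram, Hypnogram]] | None = None,
) -> tuple[pd.DataFrame, ClassificationReport | None]:
    """One AgreementStats row per sleep parameter (device, reference pairs
    per night) plus, when hypnogram pairs are given, the pooled epoch-level
    classification report."""
    rows = []
    for name in SleepParameters.PARAMETER_NAMES:
        dev = np.array([getattr(p[0], name) for p in parameter_pairs])
        ref = np.array([getattr(p[1], name) for p in parameter_pairs])
        ba = bland_altman(dev, ref)
        s = sme(dev - ref)
        icc, cat = icc_agreement(dev, ref)
        rho = spearman_rho(dev, ref)
        rows.append(
            AgreementStats(
                name, ba["bias"], ba["loa_lower"], ba["loa_upper"],
                s, mdc(s), icc, cat, rho, ba["n"],
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows]).set_index("parameter")
    epoch_report = None
    if hypnogram_pairs:
        conf = np.zeros((4, 4), dtype=int)
        for pred, ref_h in hypnogram_pairs:
            conf += confusion_and_rates(pred, ref_h).confusion
        epoch_report = report_from_confusion(conf)
    return table, epoch_report
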