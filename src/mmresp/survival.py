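"""Survival stratification and classification metrics.

Kaplan-Meier product-limit estimation, the Mantel-Haenszel (log-rank) test
with an O/E hazard ratio, ROC/AUC as Mann-Whitney concordance, confusion
metrics with the no-clinical-benefit class as the test-positive class, and
Wilcoxon tests. The estimators are implemented from their definitions;
library implementations serve only as cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalFit",
    "PerformanceSummary",
    "km_estimate",
    "km_median",
    "logrank_test",
    "roc_auc",
    "confusion_metrics",
    "wilcoxon_test",
]


@dataclass
class SurvivalFit:
    """Two-group survival comparison summary."""

    km_steps: dict[str, pd.DataFrame]
    median_pfs: dict[str, float]  # NaN encodes "not reached"
    logrank_chi2: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple[float, float]


@dataclass
class PerformanceSummary:
    """Confusion counts and rates; positive class = N-CB."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auc: float = np.nan


def km_estimate(times, events) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier product-limit estimator.

    Returns (step table with columns time / n_at_risk / n_events /
    survival, median). The median is the first time at which survival
    drops to 0.5 or below; NaN means not reached.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n = len(t)
    for ti in np.unique(t[e]):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & e).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": ti, "n_at_risk": at_risk, "n_events": d, "survival": s})
    steps = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    median = np.nan
    below = steps[steps["survival"] <= 0.5]
    if len(below):
        median = float(below["time"].iloc[0])
    return steps, median


def km_median(times, events, unreached: str = "nan") -> float:
    """KM median with a policy for unreached medians: "nan" or
    "max_observed" (substitute the largest observed time; used only for
    the model-selection PFS-separation ranking, and flagged as such)."""
    _, med = km_estimate(times, events)
    if np.isnan(med) and unreached == "max_observed":
        return float(np.max(times))
    return med


def logrank_test(times_a, events_a, times_b, events_b):
    """Mantel-Haenszel log-rank test with O/E hazard ratio.

    Returns a SurvivalFit. The hazard ratio is (O_A/E_A)/(O_B/E_B) with
    group A as numerator; its CI is on the log scale with standard error
    sqrt(1/E_A + 1/E_B).
    """
    ta = np.asarray(times_a, float)
    ea = np.asarray(events_a, bool)
    tb = np.asarray(times_b, float)
    eb = np.asarray(events_b, bool)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])

    oa = ea_exp = eb_exp = var = 0.0
    for ti in np.unique(t_all[e_all]):
        at = t_all >= ti
        n = at.sum()
        n_a = (at & grp_a).sum()
        d = int((e_all & (t_all == ti)).sum())
        d_a = int((e_all & (t_all == ti) & grp_a).sum())
        oa += d_a
        ea_exp += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    total_events = int(e_all.sum())
    ob = total_events - oa
    eb_exp = total_events - ea_exp

    steps_a, med_a = km_estimate(ta, ea)
    steps_b, med_b = km_estimate(tb, eb)
    if total_events == 0:
        return SurvivalFit(
            {"A": steps_a, "B": steps_b}, {"A": med_a, "B": med_b},
            0.0, 1.0, np.nan, (np.nan, np.nan),
        )
    chi2 = (oa - ea_exp) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, 1))
    if oa > 0 and ob > 0 and ea_exp > 0 and eb_exp > 0:
        hr = (oa / ea_exp) / (ob / eb_exp)
        se = np.sqrt(1.0 / ea_exp + 1.0 / eb_exp)
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    else:
        hr, ci = np.nan, (np.nan, np.nan)
    return SurvivalFit(
        {"A": steps_a, "B": steps_b},
        {"A": med_a, "B": med_b},
        float(chi2),
        p,
        float(hr),
        ci,
    )


def roc_auc(scores, truth, positive=True) -> tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney concordance probability with half credit
    for ties, plus the ROC curve from a threshold sweep.

    ``truth`` is boolean; ``positive`` selects which value of truth is the
    positive class (the study reports N-CB as positive).
    """
    s = np.asarray(scores, float)
    y = np.asarray(truth) == positive
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    pts = [{"fpr": 0.0, "tpr": 0.0}]
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        pts.append(
            {"fpr": float((pred & ~y).sum() / n0), "tpr": float((pred & y).sum() / n1)}
        )
    pts.append({"fpr": 1.0, "tpr": 1.0})
    return float(auc), pd.DataFrame(pts).drop_duplicates().reset_index(drop=True)


def confusion_metrics(predicted, truth, positive_label: str = "N-CB") -> PerformanceSummary:
    """Confusion counts with N-CB as the positive class: sensitivity is
    the fraction of true N-CB patients called N-CB, specificity the
    fraction of true CB patients called CB."""
    pred = np.asarray(predicted)
    tr = np.asarray(truth)
    pos_p = pred == positive_label
    pos_t = tr == positive_label
    tp = int((pos_p & pos_t).sum())
    fp = int((pos_p & ~pos_t).sum())
    tn = int((~pos_p & ~pos_t).sum())
    fn = int((~pos_p & pos_t).sum())
    sn = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    return PerformanceSummary(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sn, specificity=sp)


def wilcoxon_test(x, y=None, paired: bool = False) -> tuple[float, float]:
    """Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    Exact p for n <= 25 without ties, normal approximation with tie
    correction otherwise. All-zero paired differences give p = 1.
    """
    x = np.asarray(x, float)
    if paired:
        if y is None:
            raise ValueError("paired test needs both samples")
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        nz = d[d != 0]
        method = "exact" if len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) else "approx"
        res = stats.wilcoxon(x, y, method=method, zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    y = np.asarray(y, float)
    exact = (
        len(x) <= 25 and len(y) <= 25
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)
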