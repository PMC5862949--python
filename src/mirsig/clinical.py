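"""Survival stratification and predictive-value statistics.

Kaplan-Meier product-limit curves and the two-group log-rank test come from
lifelines; the chi-square contingency test from scipy (no continuity
correction by default); ROC AUC is the rank-based Mann-Whitney concordance
(ties counted one half) with a seeded stratified percentile bootstrap CI.
At tied times, events are processed before censorings (standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate: at each event time the number at
    risk, events, censorings, and S(t)."""

    table: pd.DataFrame  # columns: time, at_risk, events, censored, survival

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi_square: float
    p: float
    row_proportions: np.ndarray


@dataclass
class ROCResult:
    pairs: pd.DataFrame  # score, label, ranked by descending score
    auc: float
    ci: tuple[float, float]
    n_boot: int
    seed: int


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after
    their time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    et = kmf.event_table
    # drop the t=0 bookkeeping row unless someone actually has time 0
    if 0.0 not in set(times.tolist()):
        et = et[et.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame({
        "time": et.index.values.astype(float),
        "at_risk": et["at_risk"].values.astype(int),
        "events": et["observed"].values.astype(int),
        "censored": et["censored"].values.astype(int),
        "survival": [float(surv.loc[t]) for t in et.index],
    })
    return SurvivalCurve(table=table)


def logrank(group_a: tuple, group_b: tuple) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p from a
    1-df chi-square)."""
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def contingency_test(table, continuity_correction: bool = False
                     ) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction by
    default.  Per-row proportions are reported so statements like "15 of 18"
    are reproducible.  A zero margin is a hard error (use an exact test)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin; consider Fisher's exact test")
    chi2, p, _, _ = stats.chi2_contingency(table,
                                           correction=continuity_correction)
    row_prop = table / table.sum(axis=1, keepdims=True)
    return ContingencyResult(table=table.astype(int), chi_square=float(chi2),
                             p=float(p), row_proportions=row_prop)


def _auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks (ties counted one half)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """AUC of ``scores`` for the binary ``labels`` (1 = positive class) with a
    stratified percentile bootstrap confidence interval.

    Stratified resampling (positives and negatives drawn separately) keeps
    both classes present in every replicate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    auc = _auc_from_ranks(scores, labels)

    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    bp = pos[rng.integers(0, n_pos, size=(n_boot, n_pos))]
    bn = neg[rng.integers(0, n_neg, size=(n_boot, n_neg))]
    both = np.concatenate([bp, bn], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r_pos = ranks[:, :n_pos].sum(axis=1)
    boot_auc = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    lo, hi = np.percentile(boot_auc, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)

    order = np.argsort(-scores, kind="stable")
    pairs = pd.DataFrame({"score": scores[order], "label": labels[order]})
    return ROCResult(pairs=pairs, auc=float(auc), ci=(float(lo), float(hi)),
                     n_boot=n_boot, seed=seed)
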