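"""Bayesian Compound Covariate Predictor (BCCP) with leave-one-out CV.

Training: each signature gene is z-scored within the training set and gets a
weight t_i, its pooled two-sample t statistic between the nc886-high and
nc886-low classes.  A sample's compound covariate is c_j = sum_i t_i x_ij over
the standardized values.  The two classes induce Gaussian densities on c with
class means m_high, m_low and a pooled within-class variance s^2; the
posterior probability of nc886-high is the two-Gaussian Bayes rule

    P(high | c) = pi_h N(c; m_high, s^2) / [pi_h N(c; m_high, s^2)
                                            + pi_l N(c; m_low, s^2)].

Classification is tri-state: high above the upper posterior cutoff, low below
the lower cutoff, undetermined in between.  Priors default to equal (the
training panel is designed, not a population sample).  When the classifier is
applied to a cohort from another platform, each gene is z-scored within the
cohort itself: the minimal cross-platform calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("mirsig.bccp")

HIGH, LOW, UNDETERMINED = "high", "low", "undetermined"


@dataclass
class BCCPModel:
    genes: list[str]
    weights: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray
    m_high: float
    m_low: float
    s2: float
    prior_high: float = 0.5
    high_cut: float = 0.7
    low_cut: float = 0.3

    def __post_init__(self) -> None:
        if self.s2 <= 0:
            raise ValueError("pooled within-class variance must be > 0")
        if not 0 < self.prior_high < 1:
            raise ValueError("prior must be in (0, 1)")
        if not 0 < self.low_cut <= self.high_cut < 1:
            raise ValueError("cutoffs must satisfy 0 < low_cut <= high_cut < 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "weights": self.weights.tolist(),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "m_high": self.m_high, "m_low": self.m_low, "s2": self.s2,
            "prior_high": self.prior_high,
            "high_cut": self.high_cut, "low_cut": self.low_cut,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BCCPModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"], weights=np.asarray(d["weights"]),
            train_mean=np.asarray(d["train_mean"]),
            train_sd=np.asarray(d["train_sd"]),
            m_high=d["m_high"], m_low=d["m_low"], s2=d["s2"],
            prior_high=d["prior_high"],
            high_cut=d["high_cut"], low_cut=d["low_cut"],
        )


@dataclass
class ClassifiedCohort:
    """Per-patient compound covariate, posterior, and tri-state label."""

    table: pd.DataFrame  # columns: patient, c, p_high, label
    matched_genes: list[str] = field(default_factory=list)
    unmatched_genes: list[str] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["patient"], self.table["label"]))


def _class_matrices(matrix: ExpressionMatrix, labels: dict[str, str],
                    genes: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    for s in matrix.sample_ids:
        if s not in labels:
            raise ValueError(f"sample {s!r} has no class label")
        if labels[s] not in (HIGH, LOW):
            raise ValueError(f"label for {s!r} must be high|low")
    index = matrix.gene_index()
    rows, kept = [], []
    for g in genes:
        i = index.get(g.upper())
        if i is None:
            continue
        rows.append(i)
        kept.append(g)
    if len(kept) < len(genes):
        logger.info("fit: dropped %d signature gene(s) missing from training",
                    len(genes) - len(kept))
    if not kept:
        raise ValueError("no signature genes present in the training matrix")
    return matrix.values[rows], np.asarray(
        [labels[s] == HIGH for s in matrix.sample_ids]), kept


def fit(training: ExpressionMatrix, labels: dict[str, str],
        genes: list[str], prior_high: float = 0.5,
        high_cut: float = 0.7, low_cut: float = 0.3) -> BCCPModel:
    """Train a BCCP model from a labeled expression matrix."""
    values, is_high, kept = _class_matrices(training, labels, genes)
    n_h, n_l = int(is_high.sum()), int((~is_high).sum())
    if n_h < 2 or n_l < 2:
        raise ValueError(f"both classes need >= 2 samples (high={n_h}, low={n_l})")

    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    informative = sd > 0
    if not informative.all():
        logger.info("fit: dropped %d zero-variance gene(s)",
                    int((~informative).sum()))
        values, mean, sd = values[informative], mean[informative], sd[informative]
        kept = [g for g, k in zip(kept, informative) if k]
    if not kept:
        raise ValueError("no informative signature genes")
    x = (values - mean[:, None]) / sd[:, None]

    xh, xl = x[:, is_high], x[:, ~is_high]
    vh = xh.var(axis=1, ddof=1)
    vl = xl.var(axis=1, ddof=1)
    sp2 = ((n_h - 1) * vh + (n_l - 1) * vl) / (n_h + n_l - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (xh.mean(axis=1) - xl.mean(axis=1)) / np.sqrt(
            sp2 * (1.0 / n_h + 1.0 / n_l))
    t = np.where(np.isfinite(t), t, 0.0)

    c = t @ x
    ch, cl = c[is_high], c[~is_high]
    m_high, m_low = float(ch.mean()), float(cl.mean())
    s2 = float(((n_h - 1) * ch.var(ddof=1) + (n_l - 1) * cl.var(ddof=1))
               / (n_h + n_l - 2))
    if s2 <= 0:
        raise ValueError("zero within-class variance of the compound covariate")
    return BCCPModel(genes=kept, weights=t, train_mean=mean, train_sd=sd,
                     m_high=m_high, m_low=m_low, s2=s2,
                     prior_high=prior_high, high_cut=high_cut, low_cut=low_cut)


def posterior(model: BCCPModel, c: float | np.ndarray) -> float | np.ndarray:
    """P(nc886-high | compound covariate c) under the two-Gaussian model."""
    c = np.asarray(c, dtype=float)
    s = np.sqrt(model.s2)
    num = model.prior_high * stats.norm.pdf(c, model.m_high, s)
    den = num + (1 - model.prior_high) * stats.norm.pdf(c, model.m_low, s)
    with np.errstate(invalid="ignore"):
        p = num / den
    # far in a tail both densities underflow; fall back to the log-odds form
    bad = ~np.isfinite(p) | (den == 0)
    if np.any(bad):
        from scipy.special import expit
        log_odds = (np.log(model.prior_high / (1 - model.prior_high))
                    + (stats.norm.logpdf(c, model.m_high, s)
                       - stats.norm.logpdf(c, model.m_low, s)))
        p = np.where(bad, expit(log_odds), p)
    return float(p) if p.ndim == 0 else p


def compound_covariate(model: BCCPModel, matrix: ExpressionMatrix,
                       internal_standardization: bool = True) -> np.ndarray:
    """Compound covariates for the samples of ``matrix``.

    With ``internal_standardization`` each gene is z-scored within this
    matrix (cross-platform use); otherwise the training constants are used.
    Raises if more than half of the model genes are unmatched.
    """
    index = matrix.gene_index()
    rows, weights, means, sds, matched, unmatched = [], [], [], [], [], []
    for g, w, mu, sd in zip(model.genes, model.weights,
                            model.train_mean, model.train_sd):
        i = index.get(g.upper())
        if i is None:
            unmatched.append(g)
            continue
        rows.append(i)
        weights.append(w)
        means.append(mu)
        sds.append(sd)
        matched.append(g)
    if len(matched) * 2 < len(model.genes):
        raise ValueError(
            f"only {len(matched)} of {len(model.genes)} model genes matched; "
            "platform mismatch"
        )
    values = matrix.values[rows]
    if internal_standardization:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        ok = sd[:, 0] > 0
        if not ok.all():
            logger.info("compound_covariate: dropped %d zero-variance gene(s)",
                        int((~ok).sum()))
        x = np.where(ok[:, None], (values - mu) / np.where(sd == 0, 1, sd), 0.0)
    else:
        x = ((values - np.asarray(means)[:, None])
             / np.asarray(sds)[:, None])
    return np.asarray(weights) @ x


def posterior_from_expression(model: BCCPModel, matrix: ExpressionMatrix,
                              internal_standardization: bool = True
                              ) -> np.ndarray:
    """Posterior P(high) per sample of ``matrix``."""
    return posterior(model, compound_covariate(
        model, matrix, internal_standardization=internal_standardization))


def loocv(training: ExpressionMatrix, labels: dict[str, str],
          genes: list[str], prior_high: float = 0.5
          ) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validation with full model re-derivation per fold.

    The held-out sample is called high when its posterior exceeds 0.5.  A fold
    whose training remainder loses a whole class is skipped and reported.
    Returns (misclassification rate over evaluated folds, per-sample calls).
    """
    records = []
    errors = 0
    evaluated = 0
    for held in training.sample_ids:
        rest = [s for s in training.sample_ids if s != held]
        rest_idx = [training.sample_ids.index(s) for s in rest]
        sub = ExpressionMatrix(
            gene_ids=list(training.gene_ids), sample_ids=rest,
            values=training.values[:, rest_idx],
            sample_condition={s: training.sample_condition[s] for s in rest},
            sample_replicate={s: training.sample_replicate[s] for s in rest},
        )
        rest_labels = {s: labels[s] for s in rest}
        classes = set(rest_labels.values())
        if len(classes) < 2 or any(
                sum(1 for v in rest_labels.values() if v == c) < 2
                for c in (HIGH, LOW)):
            records.append({"sample": held, "call": "skipped",
                            "p_high": np.nan, "correct": np.nan})
            logger.info("loocv: fold for %s skipped (class lost)", held)
            continue
        model = fit(sub, rest_labels, genes, prior_high=prior_high)
        i = training.sample_ids.index(held)
        held_matrix = ExpressionMatrix(
            gene_ids=list(training.gene_ids), sample_ids=[held],
            values=training.values[:, [i]],
            sample_condition={held: training.sample_condition[held]},
            sample_replicate={held: training.sample_replicate[held]},
        )
        # one held-out sample cannot be z-scored against itself: use the
        # fold's training standardization
        p = float(posterior_from_expression(
            model, held_matrix, internal_standardization=False)[0])
        call = HIGH if p > 0.5 else LOW
        correct = call == labels[held]
        evaluated += 1
        errors += not correct
        records.append({"sample": held, "call": call, "p_high": p,
                        "correct": bool(correct)})
    if evaluated == 0:
        raise ValueError("no evaluable LOOCV folds")
    return errors / evaluated, pd.DataFrame.from_records(records)


def classify_cohort(model: BCCPModel, cohort: ExpressionMatrix,
                    high_cut: float | None = None,
                    low_cut: float | None = None) -> ClassifiedCohort:
    """Tri-state classification of a cohort with cohort-internal gene
    standardization.  Posterior > high_cut -> high, < low_cut -> low,
    otherwise undetermined."""
    hc = model.high_cut if high_cut is None else high_cut
    lc = model.low_cut if low_cut is None else low_cut
    if not 0 < lc <= hc < 1:
        raise ValueError("cutoffs must satisfy 0 < low_cut <= high_cut < 1")
    index = cohort.gene_index()
    matched = [g for g in model.genes if g.upper() in index]
    unmatched = [g for g in model.genes if g.upper() not in index]
    c = compound_covariate(model, cohort, internal_standardization=True)
    p = posterior(model, c)
    label = np.where(p > hc, HIGH, np.where(p < lc, LOW, UNDETERMINED))
    table = pd.DataFrame({"patient": cohort.sample_ids, "c": c,
                          "p_high": p, "label": label})
    return ClassifiedCohort(table=table, matched_genes=matched,
                            unmatched_genes=unmatched)
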