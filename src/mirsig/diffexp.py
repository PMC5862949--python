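"""Per-gene two-condition contrasts and fold-change/significance selection.

The contrast statistic is the classical pooled-variance two-sample t on log2
values (Welch available by option); the fold change is
mean(log2 treatment) - mean(log2 reference).  No multiple-testing correction
is applied by default: selection filters on raw p plus fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("mirsig.diffexp")


@dataclass
class ContrastResult:
    """Per-gene log2 fold change, t statistic, and two-sided p for one contrast.

    ``degenerate`` flags genes with zero pooled variance but unequal means
    (t undefined); they are excluded from threshold selection.
    """

    name: str
    genes: list[str]
    fc: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_treatment: int
    n_reference: int
    degenerate: np.ndarray

    @property
    def df(self) -> int:
        return self.n_treatment + self.n_reference - 2

    def gene_index(self) -> dict[str, int]:
        return {g.upper(): i for i, g in enumerate(self.genes)}

    def negated(self, name: str | None = None) -> "ContrastResult":
        """The same contrast with treatment and reference swapped."""
        return ContrastResult(
            name=name or f"-{self.name}", genes=list(self.genes),
            fc=-self.fc, t=-self.t, p=self.p.copy(),
            n_treatment=self.n_reference, n_reference=self.n_treatment,
            degenerate=self.degenerate.copy(),
        )


@dataclass
class CorrelationReport:
    """Pearson correlation of fold changes across two contrasts."""

    gene_count: int
    pearson_r: float
    p_value: float
    selection_rule: str


def contrast(matrix: ExpressionMatrix, treatment: str, reference: str,
             welch: bool = False, name: str | None = None) -> ContrastResult:
    """Two-sample contrast of ``treatment`` versus ``reference`` conditions.

    Both conditions need >= 2 replicates.  p is two-sided from the t
    distribution with n1 + n2 - 2 degrees of freedom (pooled variance).
    """
    ti = matrix.sample_indices(treatment)
    ri = matrix.sample_indices(reference)
    if len(ti) < 2 or len(ri) < 2:
        raise ValueError(
            f"conditions need >= 2 replicates: {treatment}={len(ti)}, "
            f"{reference}={len(ri)}"
        )
    xt = matrix.values[:, ti]
    xr = matrix.values[:, ri]
    n1, n2 = xt.shape[1], xr.shape[1]
    fc = xt.mean(axis=1) - xr.mean(axis=1)

    if welch:
        t, p = stats.ttest_ind(xt, xr, axis=1, equal_var=False)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, np.sign(fc) * np.inf, t)
        p = np.where(degenerate, 0.0, p)
        zero_both = degenerate & (fc == 0)
        t[zero_both], p[zero_both] = 0.0, 1.0
        degenerate &= fc != 0
    else:
        v1 = xt.var(axis=1, ddof=1)
        v2 = xr.var(axis=1, ddof=1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = fc / se
        degenerate = (se == 0) & (fc != 0)
        t = np.where(se == 0, np.where(fc == 0, 0.0, np.sign(fc) * np.inf), t)
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
        p = np.where((se == 0) & (fc == 0), 1.0, p)
    if degenerate.any():
        logger.info("contrast %s vs %s: %d gene(s) with zero pooled variance "
                    "and unequal means flagged degenerate",
                    treatment, reference, int(degenerate.sum()))
    return ContrastResult(
        name=name or f"{treatment}_vs_{reference}",
        genes=list(matrix.gene_ids), fc=fc, t=np.asarray(t, dtype=float),
        p=np.asarray(p, dtype=float), n_treatment=n1, n_reference=n2,
        degenerate=degenerate,
    )


def select_significant(result: ContrastResult, p_cut: float,
                       fc_cut: float) -> list[str]:
    """Genes with p < p_cut and |log2 fc| >= fc_cut, in input order.

    Degenerate genes (zero pooled variance, unequal means) are excluded.
    """
    if p_cut <= 0 or fc_cut < 0:
        raise ValueError("thresholds must be positive (fc_cut may be 0)")
    keep = (result.p < p_cut) & (np.abs(result.fc) >= fc_cut) & ~result.degenerate
    selected = [g for g, k in zip(result.genes, keep) if k]
    logger.info("select_significant(%s): %d of %d genes pass p<%g, |fc|>=%g",
                result.name, len(selected), len(result.genes), p_cut, fc_cut)
    return selected


def venn(list_a: list[str], list_b: list[str]) -> tuple[int, int, int]:
    """(|A only|, |A intersect B|, |B only|) over deduplicated symbols."""
    a = {g.upper() for g in list_a}
    b = {g.upper() for g in list_b}
    return len(a - b), len(a & b), len(b - a)


def correlate_contrasts(result_a: ContrastResult, result_b: ContrastResult,
                        p_cut: float = 0.05) -> CorrelationReport:
    """Pearson correlation of fold changes over genes significant in BOTH
    contrasts (p < p_cut, no fc cutoff); p from the regression F statistic."""
    idx_b = result_b.gene_index()
    pairs = []
    for i, g in enumerate(result_a.genes):
        j = idx_b.get(g.upper())
        if j is None:
            continue
        if result_a.p[i] < p_cut and result_b.p[j] < p_cut:
            pairs.append((result_a.fc[i], result_b.fc[j]))
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} genes significant in both contrasts; "
            "correlation undefined (need >= 3)"
        )
    x, y = np.asarray(pairs).T
    fit = stats.linregress(x, y)
    return CorrelationReport(
        gene_count=len(pairs),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        selection_rule=f"p < {p_cut} in both contrasts, no fc cutoff",
    )
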