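"""Divergent-gene and signature-gene selection, clustering, and target filtering.

Fold thresholds given as linear ratios (1.3, 1.5) are applied on the log2
scale as |log2 fc| >= log2(threshold); all threshold comparisons are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffexp import ContrastResult
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("mirsig.signature")


@dataclass
class SignatureGeneList:
    """Genes passing the per-experiment fold-change rule, with their evidence.

    ``table`` holds the oriented per-experiment fold changes, the number of
    passing experiments, and the consensus sign for every selected gene;
    ``rule`` records the thresholds verbatim.
    """

    genes: list[str]
    table: pd.DataFrame
    rule: dict

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClusteringResult:
    """Two-way average-linkage clustering on 1 - Pearson correlation."""

    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    sample_partition: dict[str, int]
    dropped_genes: list[str]


def divergent_genes(matrix: ExpressionMatrix, experiments: list[str],
                    fold_threshold: float = 1.5,
                    min_experiments: int = 1) -> list[str]:
    """Genes diverging from the across-sample median in enough experiments.

    ``experiments`` lists condition labels; an experiment's deviation for a
    gene is the mean over its replicate samples of (log2 value - the gene's
    median across ALL samples).  A gene passes if |deviation| >=
    log2(fold_threshold) in at least ``min_experiments`` experiments.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    med = np.median(matrix.values, axis=1, keepdims=True)
    centered = matrix.values - med
    cut = np.log2(fold_threshold)
    n_pass = np.zeros(matrix.n_genes, dtype=int)
    for cond in experiments:
        idx = matrix.sample_indices(cond)
        if len(idx) == 0:
            raise ValueError(f"no samples for experiment condition {cond!r}")
        dev = centered[:, idx].mean(axis=1)
        n_pass += np.abs(dev) >= cut
    keep = n_pass >= min_experiments
    selected = [g for g, k in zip(matrix.gene_ids, keep) if k]
    logger.info("divergent_genes: %d of %d genes diverge >=%g-fold in >=%d "
                "experiment(s)", len(selected), matrix.n_genes,
                fold_threshold, min_experiments)
    return selected


def signature_genes(contrasts: list[ContrastResult],
                    orientations: list[int] | None = None,
                    fold_threshold: float = 1.3,
                    min_experiments: int = 3,
                    sign_consistent: bool = True) -> SignatureGeneList:
    """Signature genes: |oriented log2 fc| >= log2(fold_threshold) in at
    least ``min_experiments`` contrasts, with a consistent sign across the
    passing contrasts.

    ``orientations`` (+1/-1 per contrast) flips knockdown-style contrasts so
    every fold change points toward the nc886-high direction.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if orientations is None:
        orientations = [1] * len(contrasts)
    if len(orientations) != len(contrasts):
        raise ValueError("need one orientation per contrast")
    shared = set(g.upper() for g in contrasts[0].genes)
    for c in contrasts[1:]:
        shared &= {g.upper() for g in c.genes}
    universe = [g for g in contrasts[0].genes if g.upper() in shared]
    cut = np.log2(fold_threshold)

    indexes = [c.gene_index() for c in contrasts]
    fc = np.column_stack([
        o * c.fc[[idx[g.upper()] for g in universe]]
        for c, o, idx in zip(contrasts, orientations, indexes)
    ])
    passes = np.abs(fc) >= cut
    n_pass = passes.sum(axis=1)
    enough = n_pass >= min_experiments
    if sign_consistent:
        sign_at_pass = np.sign(fc) * passes
        pos = (sign_at_pass > 0).sum(axis=1)
        neg = (sign_at_pass < 0).sum(axis=1)
        consistent = (pos == 0) | (neg == 0)
        keep = enough & consistent
    else:
        keep = enough
    genes = [g for g, k in zip(universe, keep) if k]
    consensus = np.sign(fc.sum(axis=1))
    table = pd.DataFrame(
        fc[keep], index=genes,
        columns=[c.name for c in contrasts],
    )
    table["n_pass"] = n_pass[keep]
    table["sign"] = consensus[keep].astype(int)
    rule = {"fold_threshold": fold_threshold, "log2_cut": float(cut),
            "min_experiments": min_experiments,
            "sign_consistent": sign_consistent,
            "orientations": list(orientations)}
    logger.info("signature_genes: %d of %d genes pass |fc|>=%g-fold in >=%d "
                "oriented experiments", len(genes), len(universe),
                fold_threshold, min_experiments)
    return SignatureGeneList(genes=genes, table=table, rule=rule)


def signature_to_collection(sig: SignatureGeneList,
                            name: str = "SIGNATURE") -> GeneSetCollection:
    """Export the signature as a one-set collection (GMT-ready)."""
    return GeneSetCollection(name=name, sets={name: list(sig.genes)})


def hierarchical_cluster(matrix: ExpressionMatrix,
                         genes: list[str]) -> ClusteringResult:
    """Median-center per gene, then agglomerate genes and samples
    independently with average linkage on 1 - Pearson correlation distance.

    The two-group sample partition cuts the sample dendrogram at its last
    merge.  Zero-variance genes (uninformative for correlation) are dropped
    with a log entry.
    """
    index = matrix.gene_index()
    rows = [index[g.upper()] for g in genes if g.upper() in index]
    if len(rows) < 2 or matrix.n_samples < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    values = matrix.values[rows]
    values = values - np.median(values, axis=1, keepdims=True)
    kept_genes = [matrix.gene_ids[i] for i in rows]

    var = values.var(axis=1)
    dropped = [g for g, v in zip(kept_genes, var) if v == 0]
    if dropped:
        logger.info("hierarchical_cluster: dropped %d zero-variance gene(s)",
                    len(dropped))
        keep = var > 0
        values = values[keep]
        kept_genes = [g for g, k in zip(kept_genes, keep) if k]
    if len(kept_genes) < 2:
        raise ValueError("fewer than 2 informative genes after centering")
    sample_vals = values.T
    if (sample_vals.var(axis=1) == 0).any():
        raise ValueError("zero-variance sample over the selected genes")

    gene_link = linkage(pdist(values, metric="correlation"), method="average")
    sample_link = linkage(pdist(sample_vals, metric="correlation"),
                          method="average")
    gene_order = [kept_genes[i] for i in leaves_list(gene_link)]
    sample_order = [matrix.sample_ids[i] for i in leaves_list(sample_link)]
    partition = fcluster(sample_link, t=2, criterion="maxclust")
    return ClusteringResult(
        gene_order=gene_order, sample_order=sample_order,
        gene_linkage=gene_link, sample_linkage=sample_link,
        sample_partition=dict(zip(matrix.sample_ids, partition.tolist())),
        dropped_genes=dropped,
    )


def candidate_targets(kd_contrast: ContrastResult,
                      induced_contrast: ContrastResult,
                      mir_sets: GeneSetCollection | dict[str, list[str]],
                      p_cut: float = 0.05) -> list[str]:
    """Candidate miRNA target genes: significantly decreased under knockdown,
    significantly increased under induction, and a member of at least one of
    the supplied MIR sets."""
    sets = mir_sets.sets if isinstance(mir_sets, GeneSetCollection) else mir_sets
    if not sets:
        raise ValueError("empty MIR set selection")
    members: set[str] = set()
    for genes in sets.values():
        members.update(g.upper() for g in genes)
    idx_ind = induced_contrast.gene_index()
    out = []
    for i, g in enumerate(kd_contrast.genes):
        j = idx_ind.get(g.upper())
        if j is None:
            continue
        if (kd_contrast.p[i] < p_cut and kd_contrast.fc[i] < 0
                and induced_contrast.p[j] < p_cut and induced_contrast.fc[j] > 0
                and g.upper() in members):
            out.append(g)
    logger.info("candidate_targets: %d gene(s) down in kd, up in induction, "
                "and in a selected MIR set", len(out))
    return out
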