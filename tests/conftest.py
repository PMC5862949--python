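import numpy as np
import pytest

from mirsig.diffexp import ContrastResult
from mirsig.io import ExpressionMatrix


def make_contrast(genes, fc, p=None, t=None, name="c",
                  n_treatment=3, n_reference=3):
    """Assemble a ContrastResult directly from arrays (for unit fixtures)."""
    fc = np.asarray(fc, dtype=float)
    n = len(fc)
    return ContrastResult(
        name=name, genes=list(genes), fc=fc,
        t=np.zeros(n) if t is None else np.asarray(t, dtype=float),
        p=np.zeros(n) if p is None else np.asarray(p, dtype=float),
        n_treatment=n_treatment, n_reference=n_reference,
        degenerate=np.zeros(n, dtype=bool),
    )


def make_matrix(values, conditions, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        sample_condition=dict(zip(sample_ids, conditions)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def two_group_matrix(rng):
    """50 genes, 3 treatment + 3 reference samples, pure noise."""
    values = rng.normal(8, 1, size=(50, 6))
    return make_matrix(values, ["trt"] * 3 + ["ref"] * 3)
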