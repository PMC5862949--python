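"""Synthetic expression experiments and patient cohorts with planted ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: gene-level Gaussian log2 intensities (homoscedastic noise), a
replicated two-condition experiment design with additive log2 shifts planted on
the member genes of chosen gene sets, and a patient cohort whose survival
hazard and chemo-resistance probability depend on a latent subtype that also
drives signature-gene expression.  Every generator returns a truth record from
which all planted sets, genes, and labels are recoverable.

All randomness flows from a single integer seed through ``numpy``
``SeedSequence`` substreams, so identical designs yield identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

#: Default weak pathway-wide log2 shift applied to every miRNA-target gene in
#: the nc886-high condition of the default study.  Emulates the observed
#: global suppression of the miRNA pathway, under which the large majority of
#: target sets are collectively elevated rather than a handful.
BACKGROUND_SHIFT = 0.15

#: Default extra log2 shift on the focal (strongly affected) target sets, on
#: top of the background shift, for a total focal shift of 0.5.
FOCAL_EXTRA_SHIFT = 0.35


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def default_gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def random_collection(name: str, n_sets: int, set_size: int,
                      gene_ids: list[str], seed: int) -> GeneSetCollection:
    """A collection of ``n_sets`` sets of ``set_size`` genes sampled uniformly
    (without replacement within a set) from the gene universe.  Sets may
    overlap, as real target-site collections do."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_ids)
    sets = {
        f"{name}_SET{i:04d}": list(rng.choice(genes, size=set_size, replace=False))
        for i in range(n_sets)
    }
    return GeneSetCollection(name=name, sets=sets)


@dataclass
class ExperimentDesign:
    """A replicated multi-condition expression experiment with planted shifts.

    ``conditions`` maps each condition label to its nc886 orientation
    ("high" or "low").  ``planted`` maps a condition label to a list of
    (set-names, delta) groups; a gene's shift in that condition is the sum of
    the deltas of all groups whose sets contain it.
    """

    conditions: dict[str, str]
    n_genes: int = 10_000
    replicates_per_condition: int = 3
    collection: GeneSetCollection | None = None
    planted: dict[str, list[tuple[list[str], float]]] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        for cond, orient in self.conditions.items():
            if orient not in ("high", "low"):
                raise ValueError(f"condition {cond!r}: orientation must be high|low")
        for cond, groups in self.planted.items():
            if cond not in self.conditions:
                raise ValueError(f"planted condition {cond!r} not in design")
            for set_names, delta in groups:
                if not np.isfinite(delta):
                    raise ValueError("planted shift delta must be finite")
                if self.collection is None:
                    raise ValueError("planted sets require a collection")
                missing = [s for s in set_names if s not in self.collection.sets]
                if missing:
                    raise ValueError(
                        f"planted set(s) absent from collection: {missing}"
                    )


def generate_experiment(design: ExperimentDesign) -> tuple[ExpressionMatrix, dict]:
    """Simulate log2 intensities for every condition of the design.

    Per gene g a baseline b_g ~ N(baseline_mean, baseline_sd^2) is drawn once;
    each sample value is b_g + shift(condition, g) + N(0, noise_sd^2).
    """
    rng_base, rng_noise = _rngs(design.seed, 2)
    gene_ids = default_gene_ids(design.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    baseline = rng_base.normal(design.baseline_mean, design.baseline_sd,
                               size=design.n_genes)

    shift = {cond: np.zeros(design.n_genes) for cond in design.conditions}
    truth_planted: dict[str, list[dict]] = {}
    for cond, groups in design.planted.items():
        truth_planted[cond] = []
        for set_names, delta in groups:
            # a gene in several sets of one planted group is shifted once
            genes: set[str] = set()
            for set_name in set_names:
                for g in design.collection.sets[set_name]:
                    key = g if g in gene_pos else g.upper()
                    if key in gene_pos:
                        genes.add(key)
            for g in genes:
                shift[cond][gene_pos[g]] += delta
            truth_planted[cond].append(
                {"sets": list(set_names), "delta": float(delta),
                 "genes": sorted(genes)}
            )

    sample_ids: list[str] = []
    sample_condition: dict[str, str] = {}
    sample_replicate: dict[str, int] = {}
    columns = []
    for cond in design.conditions:
        for r in range(design.replicates_per_condition):
            sid = f"{cond}_r{r + 1}"
            sample_ids.append(sid)
            sample_condition[sid] = cond
            sample_replicate[sid] = r + 1
            columns.append(baseline + shift[cond]
                           + rng_noise.normal(0.0, design.noise_sd, design.n_genes))
    values = np.column_stack(columns)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values,
                              sample_condition, sample_replicate)
    truth = {
        "seed": design.seed,
        "conditions": dict(design.conditions),
        "noise_sd": design.noise_sd,
        "planted": truth_planted,
    }
    return matrix, truth


def study_experiment(collection: GeneSetCollection, focal_sets: list[str],
                     orientation: str = "high", seed: int = 0,
                     n_genes: int = 10_000, replicates: int = 3,
                     noise_sd: float = 0.5,
                     background_shift: float = BACKGROUND_SHIFT,
                     focal_extra_shift: float = FOCAL_EXTRA_SHIFT,
                     label: str = "experiment") -> ExperimentDesign:
    """The default two-condition study experiment.

    The treated condition carries the planted structure: a weak pathway-wide
    shift on the members of every set in the collection plus an extra shift on
    the focal sets.  ``orientation`` says whether the treated condition is
    nc886-high (ectopic expression / TGF-beta style) or nc886-low (knockdown
    style); the planted shift is always applied to the nc886-high side, so a
    knockdown experiment shows the mirrored pattern in its contrast.
    """
    if orientation not in ("high", "low"):
        raise ValueError("orientation must be high|low")
    treated, control = f"{label}_treated", f"{label}_control"
    if orientation == "high":
        conditions = {treated: "high", control: "low"}
        high_cond = treated
    else:
        conditions = {treated: "low", control: "high"}
        high_cond = control
    planted: list[tuple[list[str], float]] = []
    if background_shift:
        planted.append((list(collection.sets), background_shift))
    if focal_sets:
        planted.append((list(focal_sets), focal_extra_shift))
    return ExperimentDesign(
        conditions=conditions, n_genes=n_genes,
        replicates_per_condition=replicates, collection=collection,
        planted={high_cond: planted}, noise_sd=noise_sd, seed=seed,
    )


def study_panel(collection: GeneSetCollection, focal_sets: list[str],
                orientations: dict[str, str], seed: int = 0,
                n_genes: int = 10_000, replicates: int = 3,
                noise_sd: float = 0.5,
                background_shift: float = BACKGROUND_SHIFT,
                focal_extra_shift: float = FOCAL_EXTRA_SHIFT
                ) -> tuple[ExpressionMatrix, dict]:
    """A multi-experiment array panel sharing per-gene baselines.

    ``orientations`` maps each experiment label to the nc886 orientation of
    its treated condition.  All experiments are drawn as one design (a single
    baseline per gene, as on one array platform), so samples can be pooled
    across experiments for median-centred analyses such as divergent-gene
    selection and two-way clustering.  Returns the pooled matrix with
    conditions ``<label>_treated`` / ``<label>_control`` and the truth record.
    """
    conditions: dict[str, str] = {}
    planted: dict[str, list[tuple[list[str], float]]] = {}
    for label, orient in orientations.items():
        if orient not in ("high", "low"):
            raise ValueError(f"{label}: orientation must be high|low")
        other = "low" if orient == "high" else "high"
        conditions[f"{label}_treated"] = orient
        conditions[f"{label}_control"] = other
        high_cond = f"{label}_treated" if orient == "high" else f"{label}_control"
        groups: list[tuple[list[str], float]] = []
        if background_shift:
            groups.append((list(collection.sets), background_shift))
        if focal_sets:
            groups.append((list(focal_sets), focal_extra_shift))
        planted[high_cond] = groups
    design = ExperimentDesign(
        conditions=conditions, n_genes=n_genes,
        replicates_per_condition=replicates, collection=collection,
        planted=planted, noise_sd=noise_sd, seed=seed)
    return generate_experiment(design)


@dataclass
class CohortDesign:
    """A synthetic patient cohort with a latent nc886-high/low subtype.

    The subtype is Bernoulli(``subtype_prevalence``); signature genes are
    shifted by ``delta_sig`` (times an optional per-gene sign) in nc886-high
    patients; overall survival is exponential with hazard
    ``baseline_hazard * hazard_ratio**is_high`` (per month) under independent
    exponential censoring tuned to ``censoring_rate``; chemo response is
    resistant with a subtype-specific probability.
    """

    n_patients: int = 285
    subtype_prevalence: float = 0.5
    n_genes: int = 1000
    signature_genes: list[str] | None = None
    n_signature_genes: int = 118
    delta_sig: float = 1.0
    signature_signs: np.ndarray | None = None
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    baseline_hazard: float = 0.02
    hazard_ratio: float = 3.0
    rfs_hazard_multiplier: float = 1.5
    censoring_rate: float = 0.3
    p_resistant_high: float = 0.15
    p_resistant_low: float = 0.02
    p_unknown: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subtype_prevalence", "censoring_rate", "p_resistant_high",
                     "p_resistant_low", "p_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.signature_genes is None:
            self.signature_genes = [f"SIG{i:04d}" for i in range(self.n_signature_genes)]
        self.n_signature_genes = len(self.signature_genes)
        if self.signature_signs is None:
            self.signature_signs = np.ones(self.n_signature_genes)
        self.signature_signs = np.asarray(self.signature_signs, dtype=float)
        if self.signature_signs.shape != (self.n_signature_genes,):
            raise ValueError("signature_signs must match signature_genes length")

    def gene_ids(self) -> list[str]:
        n_bg = max(self.n_genes - self.n_signature_genes, 0)
        return list(self.signature_genes) + [f"BG{i:05d}" for i in range(n_bg)]


def _censoring_scale(hazards: np.ndarray, rate: float) -> float:
    """Exponential censoring rate lambda_c with overall expected censoring
    fraction ``rate``: solves mean_i lambda_c / (lambda_c + h_i) = rate."""
    if rate <= 0:
        return 0.0

    def f(lam: float) -> float:
        return float(np.mean(lam / (lam + hazards))) - rate

    return brentq(f, 1e-12, 1e9)


def _expression_for_subtype(design: CohortDesign, is_high: np.ndarray,
                            rng: np.random.Generator,
                            sample_prefix: str) -> ExpressionMatrix:
    gene_ids = design.gene_ids()
    n_genes, n = len(gene_ids), len(is_high)
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, n_genes)
    effect = np.zeros(n_genes)
    effect[: design.n_signature_genes] = design.delta_sig * design.signature_signs
    values = (baseline[:, None]
              + np.outer(effect, is_high.astype(float))
              + rng.normal(0.0, design.noise_sd, size=(n_genes, n)))
    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    condition = {s: ("high" if h else "low") for s, h in zip(sample_ids, is_high)}
    return ExpressionMatrix(gene_ids, sample_ids, values, condition)


def generate_cohort(design: CohortDesign) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Simulate expression, survival, and chemo response for a cohort."""
    rng_sub, rng_expr, rng_surv, rng_chemo = _rngs(design.seed, 4)
    n = design.n_patients
    is_high = rng_sub.random(n) < design.subtype_prevalence
    matrix = _expression_for_subtype(design, is_high, rng_expr, "P")

    hazards = design.baseline_hazard * np.where(is_high, design.hazard_ratio, 1.0)
    os_true = rng_surv.exponential(1.0 / hazards)
    rfs_hazards = hazards * design.rfs_hazard_multiplier
    rfs_true = rng_surv.exponential(1.0 / rfs_hazards)
    lam_c = _censoring_scale(hazards, design.censoring_rate)
    if lam_c > 0:
        cens_os = rng_surv.exponential(1.0 / lam_c, size=n)
        cens_rfs = rng_surv.exponential(1.0 / lam_c, size=n)
    else:
        cens_os = np.full(n, np.inf)
        cens_rfs = np.full(n, np.inf)
    os_time = np.minimum(os_true, cens_os)
    os_event = (os_true <= cens_os).astype(int)
    rfs_time = np.minimum(rfs_true, cens_rfs)
    rfs_event = (rfs_true <= cens_rfs).astype(int)

    p_res = np.where(is_high, design.p_resistant_high, design.p_resistant_low)
    resistant = rng_chemo.random(n) < p_res
    unknown = rng_chemo.random(n) < design.p_unknown
    chemo = np.where(unknown, "unknown",
                     np.where(resistant, "resistant", "sensitive"))

    clinical = ClinicalTable(pd.DataFrame({
        "patient_id": matrix.sample_ids,
        "os_time": os_time,
        "os_event": os_event,
        "rfs_time": rfs_time,
        "rfs_event": rfs_event,
        "chemo_response": chemo,
    }))
    truth = {
        "seed": design.seed,
        "subtype": {s: ("high" if h else "low")
                    for s, h in zip(matrix.sample_ids, is_high)},
        "signature_genes": list(design.signature_genes),
        "signature_signs": design.signature_signs.tolist(),
        "delta_sig": design.delta_sig,
        "hazard_ratio": design.hazard_ratio,
        "baseline_hazard": design.baseline_hazard,
        "p_resistant_high": design.p_resistant_high,
        "p_resistant_low": design.p_resistant_low,
    }
    return matrix, clinical, truth


def generate_labeled_panel(design: CohortDesign, n_high: int, n_low: int,
                           seed: int | None = None
                           ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """A designed training panel sharing the cohort's signature-gene effects.

    Returns an expression matrix with ``n_high`` nc886-high and ``n_low``
    nc886-low samples (fixed labels, not Bernoulli) and the label map, for
    training a classifier that is then applied to ``generate_cohort`` output.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    is_high = np.array([True] * n_high + [False] * n_low)
    matrix = _expression_for_subtype(design, is_high, rng, "T")
    labels = {s: matrix.sample_condition[s] for s in matrix.sample_ids}
    return matrix, labels
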