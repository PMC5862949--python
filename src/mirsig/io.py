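"""Readers, writers, and validated containers for the formats the pipeline touches.

Expression data travel as tab-separated genes x samples tables (log2 intensities)
with a separate sample-annotation table; gene sets as GMT; clinical data and all
stage outputs as CSV with a header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mirsig.io")

CHEMO_RESPONSES = ("sensitive", "resistant", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Dense log2 expression values (genes x samples) with condition annotation.

    Invariants enforced at construction: unique gene and sample identifiers,
    finite values, and a condition label for every sample.  Missing values are
    rejected at load time, never imputed silently.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_condition: dict[str, str]
    sample_replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.sample_condition]
        if missing:
            raise ValueError(f"samples without condition annotation: {missing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing entries)")
        if not self.sample_replicate:
            self.sample_replicate = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condition_of(self, sample: str) -> str:
        return self.sample_condition[sample]

    def sample_indices(self, condition: str) -> np.ndarray:
        """Column indices of the samples annotated with ``condition``."""
        idx = [i for i, s in enumerate(self.sample_ids)
               if self.sample_condition[s] == condition]
        return np.asarray(idx, dtype=int)

    def gene_index(self) -> dict[str, int]:
        """Case-insensitive symbol -> row index map (upper-cased keys)."""
        return {g.upper(): i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MIR, TFT, Biocarta) with case-normalized members."""

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        normalized: dict[str, list[str]] = {}
        for set_name, members in self.sets.items():
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(str(m).upper(), None)
            if not seen:
                raise ValueError(f"gene set {set_name!r} is empty")
            normalized[set_name] = list(seen)
        self.sets = normalized

    def __len__(self) -> int:
        return len(self.sets)

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


@dataclass
class ClinicalTable:
    """Per-patient survival and chemotherapy-response annotation.

    Times are in months; events are 0/1; unknown chemo responses are preserved.
    """

    table: pd.DataFrame

    REQUIRED = ("patient_id", "os_time", "os_event", "rfs_time", "rfs_event",
                "chemo_response")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient identifiers")
        for col in ("os_time", "rfs_time"):
            if (df[col] < 0).any():
                raise ValueError(f"{col} contains negative times")
        for col in ("os_event", "rfs_event"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary 0/1")
        bad = set(df["chemo_response"]) - set(CHEMO_RESPONSES)
        if bad:
            raise ValueError(f"unknown chemo_response values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)


def _collapse_duplicates(df: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Collapse duplicated gene rows; 'max-mean' keeps the row with highest mean."""
    if not df.index.duplicated().any():
        return df
    if rule == "error":
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"duplicate gene rows: {dups}")
    if rule != "max-mean":
        raise ValueError(f"unknown duplicate-collapse rule {rule!r}")
    n_before = len(df)
    keep = df.assign(_mean=df.mean(axis=1))
    keep = keep.sort_values("_mean").groupby(level=0, sort=False).tail(1)
    keep = keep.drop(columns="_mean").loc[[g for g in dict.fromkeys(df.index)]]
    logger.info("collapsed duplicate gene rows: %d -> %d (rule=max-mean)",
                n_before, len(keep))
    return keep


def read_expression(path: str | Path, annotation_path: str | Path,
                    collapse: str = "max-mean") -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix plus its sample annotation.

    The matrix has a header row of sample ids and a first column of gene ids.
    The annotation table (TSV or CSV by extension) maps sample -> condition and
    replicate.  A sample without annotation or a non-numeric cell is a hard
    error naming the offender.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.empty or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    missing = raw.isna()
    if bad.values.any() or missing.values.any():
        mask = (bad | missing).values
        r, c = np.argwhere(mask)[0]
        raise FormatError(
            f"{path}: non-numeric or missing value at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    values = _collapse_duplicates(values, collapse)

    ann_path = Path(annotation_path)
    sep = "," if ann_path.suffix.lower() == ".csv" else "\t"
    ann = pd.read_csv(ann_path, sep=sep, dtype=str)
    for col in ("sample", "condition"):
        if col not in ann.columns:
            raise FormatError(f"{ann_path}: annotation missing column {col!r}")
    cond = dict(zip(ann["sample"], ann["condition"]))
    unannotated = [s for s in values.columns if s not in cond]
    if unannotated:
        raise FormatError(
            f"{ann_path}: no annotation for sample(s) {unannotated}"
        )
    if "replicate" in ann.columns:
        repl = {s: int(r) for s, r in zip(ann["sample"], ann["replicate"])}
    else:
        repl = {s: i for i, s in enumerate(values.columns)}
    return ExpressionMatrix(
        gene_ids=list(values.index),
        sample_ids=list(values.columns),
        values=values.values,
        sample_condition={s: cond[s] for s in values.columns},
        sample_replicate={s: repl[s] for s in values.columns},
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path) -> None:
    """Write the matrix as TSV and its annotation as a TSV sample table."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.10g")
    ann = pd.DataFrame({
        "sample": matrix.sample_ids,
        "condition": [matrix.sample_condition[s] for s in matrix.sample_ids],
        "replicate": [matrix.sample_replicate[s] for s in matrix.sample_ids],
    })
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member symbols, tab-separated.

    The description field is discarded and members are deduplicated per set.
    A line with fewer than 3 fields or a repeated set name is a hard error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            set_name = fields[0]
            if set_name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            members = [f for f in fields[2:] if f.strip()]
            sets[set_name] = members
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, "na", *members]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, index=False)
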