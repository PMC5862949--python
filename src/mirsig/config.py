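"""Flat key/value configuration for the pipeline.

Every numeric threshold used by the analysis is a config key.  The defaults are
the thresholds of the study the pipeline replicates: per-gene significance at
p < 0.05, a 0.5 log2 fold-change cutoff for "altered" genes, a 1.5-fold cutoff
for divergent genes, a 1.3-fold / >=3-experiment rule for signature genes, a
minimum matched set size of 5, and Bayesian posterior cutoffs of 0.7 / 0.3.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

#: Keys that every pipeline run must define.  ``run_pipeline`` refuses a config
#: that omits one of these, naming the missing key.
REQUIRED_KEYS = (
    "seed",
    "p_cut",
    "fc_cut",
    "divergent_fold",
    "signature_fold",
    "signature_min_experiments",
    "min_set_size",
    "high_cut",
    "low_cut",
)


def default_config() -> dict:
    """A complete configuration for the default synthetic study."""
    return {
        # randomness
        "seed": 0,
        # synthetic experiment panel
        "n_genes": 10_000,
        "replicates": 3,
        "noise_sd": 0.5,
        "baseline_mean": 8.0,
        "baseline_sd": 2.0,
        "n_mir_sets": 221,
        "n_tft_sets": 615,
        "set_size": 50,
        "n_focal_sets": 5,
        "focal_extra_shift": 0.35,
        "background_shift": 0.15,
        # differential expression / signature thresholds
        "p_cut": 0.05,
        "fc_cut": 0.5,
        "divergent_fold": 1.5,
        "divergent_min_experiments": 1,
        "signature_fold": 1.3,
        "signature_min_experiments": 3,
        "min_set_size": 5,
        # classifier
        "high_cut": 0.7,
        "low_cut": 0.3,
        "n_high_train": 12,
        "n_low_train": 9,
        # synthetic cohort
        "n_patients": 285,
        "subtype_prevalence": 0.5,
        "delta_sig": 1.0,
        "cohort_n_genes": 1000,
        "baseline_hazard": 0.02,
        "hazard_ratio": 3.0,
        "censoring_rate": 0.3,
        "p_resistant_high": 0.15,
        "p_resistant_low": 0.02,
        # evaluation
        "n_boot": 2000,
    }


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON flat config file."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            cfg = json.load(fh)
        else:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Check that all required threshold keys are present; return the config."""
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise KeyError(f"config is missing required key {key!r}")
    return cfg
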