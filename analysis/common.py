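"""Shared setup for the numbered analysis scripts.

All scripts analyze the same default synthetic study: four replicated
experiments (three nc886-high inductions, one knockdown) over a 10,000-gene
universe with 221 MIR and 615 TFT sets, five focal MIR sets planted on top of
a weak pathway-wide shift, and a 285-patient cohort whose latent subtype
drives signature-gene expression, survival, and chemo resistance.
"""

import json
from pathlib import Path

import numpy as np

from mirsig import diffexp, simulate
from mirsig.config import default_config
from mirsig.pipeline import EXPERIMENTS

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def write_json(name: str, payload: dict) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    path.write_text(json.dumps(payload, indent=1))
    return path


def build_study(cfg: dict | None = None):
    """Collections, the pooled array panel, and oriented contrasts."""
    cfg = cfg or default_config()
    seeds = [int(s % (2**31)) for s in
             np.random.SeedSequence(int(cfg["seed"])).generate_state(8)]
    genes = simulate.default_gene_ids(int(cfg["n_genes"]))
    mir = simulate.random_collection("MIR", int(cfg["n_mir_sets"]),
                                     int(cfg["set_size"]), genes, seed=seeds[0])
    tft = simulate.random_collection("TFT", int(cfg["n_tft_sets"]),
                                     int(cfg["set_size"]), genes, seed=seeds[1])
    focal = list(mir.sets)[: int(cfg["n_focal_sets"])]
    panel, _ = simulate.study_panel(
        mir, focal, orientations=dict(EXPERIMENTS), seed=seeds[2],
        n_genes=int(cfg["n_genes"]), replicates=int(cfg["replicates"]),
        noise_sd=float(cfg["noise_sd"]),
        background_shift=float(cfg["background_shift"]),
        focal_extra_shift=float(cfg["focal_extra_shift"]))
    contrasts, orientations = {}, []
    for label, orient in EXPERIMENTS:
        contrasts[label] = diffexp.contrast(
            panel, f"{label}_treated", f"{label}_control", name=label)
        orientations.append(1 if orient == "high" else -1)
    return cfg, mir, tft, focal, panel, contrasts, orientations
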