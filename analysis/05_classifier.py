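"""Train the Bayesian Compound Covariate Predictor on a designed panel,
estimate its error by leave-one-out cross-validation, and classify the
simulated patient cohort with the 0.7/0.3 posterior cutoffs.
"""

import json

import numpy as np

from common import RESULTS, build_study, write_json
from mirsig import bccp, simulate

cfg, mir, tft, focal, panel, contrasts, orientations = build_study()

sig_genes = json.loads((RESULTS / "04_signature.json").read_text())[
    "signature_genes"]
print(f"Using the {len(sig_genes)} signature genes from 04_signature.")

seeds = [int(s % (2**31)) for s in
         np.random.SeedSequence(int(cfg["seed"])).generate_state(8)]
design = simulate.CohortDesign(
    n_patients=cfg["n_patients"],
    subtype_prevalence=cfg["subtype_prevalence"],
    n_genes=cfg["cohort_n_genes"], signature_genes=sig_genes,
    delta_sig=cfg["delta_sig"], noise_sd=cfg["noise_sd"],
    baseline_hazard=cfg["baseline_hazard"], hazard_ratio=cfg["hazard_ratio"],
    censoring_rate=cfg["censoring_rate"],
    p_resistant_high=cfg["p_resistant_high"],
    p_resistant_low=cfg["p_resistant_low"], seed=seeds[3])
panel, labels = simulate.generate_labeled_panel(
    design, cfg["n_high_train"], cfg["n_low_train"], seed=seeds[4])

model = bccp.fit(panel, labels, sig_genes,
                 high_cut=cfg["high_cut"], low_cut=cfg["low_cut"])
rate, calls = bccp.loocv(panel, labels, sig_genes)
print(f"Training panel {cfg['n_high_train']}+{cfg['n_low_train']}: "
      f"LOOCV misclassification rate {rate:.3f}")

cohort, clin, truth = simulate.generate_cohort(design)
res = bccp.classify_cohort(model, cohort)
counts = res.table["label"].value_counts().to_dict()
det = res.table[res.table["label"] != bccp.UNDETERMINED]
agree = float((det["label"] == det["patient"].map(truth["subtype"])).mean())
print(f"Cohort n={len(res.table)}: {counts.get('high', 0)} high, "
      f"{counts.get('low', 0)} low, {counts.get('undetermined', 0)} "
      f"undetermined (cutoffs {cfg['high_cut']}/{cfg['low_cut']})")
print(f"Agreement of determined labels with the planted subtype: {agree:.1%}")

path = write_json("05_classifier.json", {
    "loocv_error": rate,
    "label_counts": counts,
    "truth_agreement": agree,
    "model_summary": {"n_genes": len(model.genes),
                      "m_high": model.m_high, "m_low": model.m_low,
                      "s2": model.s2},
})
print(f"Wrote {path}")
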