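"""Survival and chemo-resistance evaluation of the classified cohort:
Kaplan-Meier curves with the log-rank test for OS and RFS, the 2x2
chemo-response contingency table, and ROC AUC of the posterior for
predicting resistance (bootstrap CI).

Rebuilds the same cohort and classifier as 05_classifier (same seeds).
"""

import json

import numpy as np

from common import RESULTS, build_study, write_json
from mirsig import bccp, clinical, simulate

cfg, mir, tft, focal, panel, contrasts, orientations = build_study()
sig_genes = json.loads((RESULTS / "04_signature.json").read_text())[
    "signature_genes"]
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
cohort, clin, truth = simulate.generate_cohort(design)
res = bccp.classify_cohort(model, cohort)

merged = res.table.merge(clin.table, left_on="patient", right_on="patient_id")
det = merged[merged["label"] != bccp.UNDETERMINED]
hi = det[det["label"] == "high"]
lo = det[det["label"] == "low"]

summary = {}
for endpoint in ("os", "rfs"):
    stat, p = clinical.logrank(
        (hi[f"{endpoint}_time"], hi[f"{endpoint}_event"]),
        (lo[f"{endpoint}_time"], lo[f"{endpoint}_event"]))
    med_hi = clinical.km_estimate(hi[f"{endpoint}_time"],
                                  hi[f"{endpoint}_event"])
    med_lo = clinical.km_estimate(lo[f"{endpoint}_time"],
                                  lo[f"{endpoint}_event"])
    s24_hi = med_hi.survival_at(24)
    s24_lo = med_lo.survival_at(24)
    summary[f"logrank_{endpoint}"] = {"chi_square": stat, "p": p,
                                      "S24_high": s24_hi, "S24_low": s24_lo}
    print(f"{endpoint.upper()}: log-rank chi2 = {stat:.1f}, p = {p:.3g}; "
          f"24-month survival {s24_hi:.0%} (high) vs {s24_lo:.0%} (low)")

known = det[det["chemo_response"] != "unknown"]
table = [[int((known["label"].eq(g) & known["chemo_response"].eq(r)).sum())
          for r in ("resistant", "sensitive")] for g in ("high", "low")]
cont = clinical.contingency_test(table)
n_res = table[0][0] + table[1][0]
print(f"Chemo resistance: {table[0][0]} of {n_res} resistant patients "
      f"({table[0][0] / n_res:.0%}) are nc886-high; chi2 = "
      f"{cont.chi_square:.1f}, p = {cont.p:.3g}")

roc = clinical.roc_auc(
    merged[merged['chemo_response'] != 'unknown']["p_high"].values,
    merged[merged['chemo_response'] != 'unknown']["chemo_response"]
    .eq("resistant").astype(int).values,
    n_boot=cfg["n_boot"], seed=seeds[5])
print(f"ROC for resistance from the posterior: AUC = {roc.auc:.1%} "
      f"(95% bootstrap CI {roc.ci[0]:.1%}-{roc.ci[1]:.1%}, "
      f"{roc.n_boot} resamples)")

summary["chemo_contingency"] = {"table": table,
                                "chi_square": cont.chi_square, "p": cont.p}
summary["roc_auc"] = {"auc": roc.auc, "ci": list(roc.ci)}
path = write_json("06_clinical_outcomes.json", summary)
print(f"Wrote {path}")
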