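"""End-to-end pipeline driver: simulate -> contrast -> gene-set activity ->
signature -> classifier -> clinical evaluation.

``run_pipeline`` takes a flat config (dict or YAML/JSON path), runs every
stage on the default synthetic study, and writes per-stage CSV/JSON artifacts
plus a log of every threshold used.  Identical config + seed gives
byte-identical outputs.  Any stage failure aborts with the stage name and the
underlying cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bccp, clinical, diffexp, gsa, signature, simulate
from .config import load_config, validate_config
from .io import write_gmt
from .signature import signature_to_collection

logger = logging.getLogger("mirsig.pipeline")

#: The default experiment panel: three nc886-high inductions and one
#: knockdown, mirroring a multi-cell-line design with a mirrored contrast.
EXPERIMENTS = (
    ("tgfb_skov3", "high"),
    ("nc886_skov3", "high"),
    ("nc886_a2780", "high"),
    ("kd_ose80pc", "low"),
)


class PipelineError(RuntimeError):
    pass


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict[str, str]:
    """Run every stage of the synthetic study; returns stage -> artifact path."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seeds = np.random.SeedSequence(int(cfg["seed"])).generate_state(8)
    seeds = [int(s % (2**31)) for s in seeds]

    # ---- stage: simulate -------------------------------------------------
    @_stage("simulate")
    def _simulate():
        gene_ids = simulate.default_gene_ids(int(cfg["n_genes"]))
        mir = simulate.random_collection(
            "MIR", int(cfg["n_mir_sets"]), int(cfg["set_size"]), gene_ids,
            seed=seeds[0])
        tft = simulate.random_collection(
            "TFT", int(cfg["n_tft_sets"]), int(cfg["set_size"]), gene_ids,
            seed=seeds[1])
        focal = list(mir.sets)[: int(cfg["n_focal_sets"])]
        panel, truth = simulate.study_panel(
            mir, focal, orientations=dict(EXPERIMENTS), seed=seeds[2],
            n_genes=int(cfg["n_genes"]), replicates=int(cfg["replicates"]),
            noise_sd=float(cfg["noise_sd"]),
            background_shift=float(cfg["background_shift"]),
            focal_extra_shift=float(cfg["focal_extra_shift"]))
        return mir, tft, focal, panel, truth

    mir, tft, focal, panel, truth = _simulate()
    write_gmt(mir, outdir / "mir_sets.gmt")
    write_gmt(tft, outdir / "tft_sets.gmt")
    (outdir / "experiment_truth.json").write_text(json.dumps(truth, indent=1))
    artifacts["simulate"] = str(outdir / "experiment_truth.json")

    # ---- stage: contrast -------------------------------------------------
    @_stage("contrast")
    def _contrasts():
        out = {}
        for label, orient in EXPERIMENTS:
            out[label] = diffexp.contrast(
                panel, f"{label}_treated", f"{label}_control", name=label)
        return out

    contrasts = _contrasts()
    for label, res in contrasts.items():
        selected = set(diffexp.select_significant(
            res, float(cfg["p_cut"]), float(cfg["fc_cut"])))
        pd.DataFrame({
            "gene": res.genes, "fc": res.fc, "t": res.t, "p": res.p,
            "selected": [g in selected for g in res.genes],
        }).to_csv(outdir / f"contrast_{label}.csv", index=False,
                  float_format="%.10g")
    artifacts["contrast"] = str(outdir / "contrast_tgfb_skov3.csv")

    # ---- stage: gsa ------------------------------------------------------
    @_stage("gsa")
    def _gsa():
        rows = []
        profiles = {}
        for label, orient in EXPERIMENTS:
            for coll in (mir, tft):
                prof = gsa.profile_collection(
                    contrasts[label], coll,
                    min_set_size=int(cfg["min_set_size"]))
                profiles[(label, coll.name)] = prof
                dist = gsa.rank_distribution(prof)
                ranks = {n: r + 1 for r, n in enumerate(dist.set_names)}
                for name, z, m in zip(prof.set_names, prof.z, prof.m):
                    rows.append({"experiment": label, "collection": coll.name,
                                 "set": name, "m": m, "z": z,
                                 "rank": ranks[name]})
        return profiles, pd.DataFrame(rows)

    profiles, ztable = _gsa()
    ztable.to_csv(outdir / "set_zscores.csv", index=False, float_format="%.10g")
    orientations = [1 if o == "high" else -1 for _, o in EXPERIMENTS]
    ranked = gsa.rank_mirs([profiles[(lab, "MIR")] for lab, _ in EXPERIMENTS],
                           orientations)
    pd.DataFrame(ranked, columns=["set", "summed_oriented_z"]).to_csv(
        outdir / "mir_ranking.csv", index=False, float_format="%.10g")
    comparison = {}
    for coll_name in ("MIR", "TFT"):
        comp = gsa.compare_profiles(profiles[("kd_ose80pc", coll_name)],
                                    profiles[("tgfb_skov3", coll_name)])
        comparison[coll_name] = {"pearson_r": comp.pearson_r,
                                 "p_value": comp.p_value,
                                 "quadrants": comp.quadrant_counts,
                                 "n_sets": comp.n_sets}
    (outdir / "mir_vs_tft_comparison.json").write_text(
        json.dumps(comparison, indent=1))
    artifacts["gsa"] = str(outdir / "set_zscores.csv")

    # ---- stage: signature ------------------------------------------------
    @_stage("signature")
    def _signature():
        return signature.signature_genes(
            [contrasts[lab] for lab, _ in EXPERIMENTS], orientations,
            fold_threshold=float(cfg["signature_fold"]),
            min_experiments=int(cfg["signature_min_experiments"]))

    sig = _signature()
    sig.table.to_csv(outdir / "signature_genes.csv", float_format="%.10g")
    write_gmt(signature_to_collection(sig), outdir / "signature.gmt")
    artifacts["signature"] = str(outdir / "signature_genes.csv")
    if not sig.genes:
        raise PipelineError("stage 'signature' failed: empty signature")

    # ---- stage: train ----------------------------------------------------
    @_stage("train")
    def _train():
        cohort_design = simulate.CohortDesign(
            n_patients=int(cfg["n_patients"]),
            subtype_prevalence=float(cfg["subtype_prevalence"]),
            n_genes=int(cfg["cohort_n_genes"]),
            signature_genes=list(sig.genes),
            delta_sig=float(cfg["delta_sig"]),
            signature_signs=np.sign(sig.table["sign"]).replace(0, 1).values,
            noise_sd=float(cfg["noise_sd"]),
            baseline_hazard=float(cfg["baseline_hazard"]),
            hazard_ratio=float(cfg["hazard_ratio"]),
            censoring_rate=float(cfg["censoring_rate"]),
            p_resistant_high=float(cfg["p_resistant_high"]),
            p_resistant_low=float(cfg["p_resistant_low"]),
            seed=seeds[3])
        panel, labels = simulate.generate_labeled_panel(
            cohort_design, int(cfg["n_high_train"]), int(cfg["n_low_train"]),
            seed=seeds[4])
        model = bccp.fit(panel, labels, sig.genes,
                         high_cut=float(cfg["high_cut"]),
                         low_cut=float(cfg["low_cut"]))
        rate, calls = bccp.loocv(panel, labels, sig.genes)
        return cohort_design, model, rate, calls

    cohort_design, model, loocv_rate, loocv_calls = _train()
    model.to_json(outdir / "bccp_model.json")
    loocv_calls.to_csv(outdir / "loocv_calls.csv", index=False,
                       float_format="%.10g")
    artifacts["train"] = str(outdir / "bccp_model.json")

    # ---- stage: classify -------------------------------------------------
    @_stage("classify")
    def _classify():
        cohort, clin, cohort_truth = simulate.generate_cohort(cohort_design)
        classified = bccp.classify_cohort(model, cohort)
        return cohort, clin, cohort_truth, classified

    cohort, clin, cohort_truth, classified = _classify()
    classified.table.to_csv(outdir / "classification.csv", index=False,
                            float_format="%.10g")
    clin.table.to_csv(outdir / "clinical.csv", index=False,
                      float_format="%.10g")
    (outdir / "cohort_truth.json").write_text(json.dumps(cohort_truth, indent=1))
    artifacts["classify"] = str(outdir / "classification.csv")

    # ---- stage: evaluate -------------------------------------------------
    @_stage("evaluate")
    def _evaluate():
        merged = classified.table.merge(
            clin.table, left_on="patient", right_on="patient_id")
        determined = merged[merged["label"] != bccp.UNDETERMINED]
        hi = determined[determined["label"] == bccp.HIGH]
        lo = determined[determined["label"] == bccp.LOW]
        chi2_os, p_os = clinical.logrank(
            (hi["os_time"], hi["os_event"]), (lo["os_time"], lo["os_event"]))
        chi2_rfs, p_rfs = clinical.logrank(
            (hi["rfs_time"], hi["rfs_event"]), (lo["rfs_time"], lo["rfs_event"]))
        km_rows = []
        for group_name, grp in (("high", hi), ("low", lo)):
            curve = clinical.km_estimate(grp["os_time"], grp["os_event"])
            t = curve.table.assign(group=group_name)
            km_rows.append(t)
        km_table = pd.concat(km_rows, ignore_index=True)

        known = determined[determined["chemo_response"] != "unknown"]
        table = np.array([
            [(known["label"].eq("high") & known["chemo_response"].eq("resistant")).sum(),
             (known["label"].eq("high") & known["chemo_response"].eq("sensitive")).sum()],
            [(known["label"].eq("low") & known["chemo_response"].eq("resistant")).sum(),
             (known["label"].eq("low") & known["chemo_response"].eq("sensitive")).sum()],
        ])
        cont = clinical.contingency_test(table)
        merged_known = merged[merged["chemo_response"] != "unknown"]
        roc = clinical.roc_auc(
            merged_known["p_high"].values,
            merged_known["chemo_response"].eq("resistant").astype(int).values,
            n_boot=int(cfg["n_boot"]), seed=seeds[5])
        truth_labels = cohort_truth["subtype"]
        agree = determined["label"].eq(
            determined["patient"].map(truth_labels)).mean()
        summary = {
            "n_patients": int(len(merged)),
            "n_undetermined": int((merged["label"] == bccp.UNDETERMINED).sum()),
            "loocv_error": loocv_rate,
            "truth_agreement_determined": float(agree),
            "logrank_os": {"chi_square": chi2_os, "p": p_os},
            "logrank_rfs": {"chi_square": chi2_rfs, "p": p_rfs},
            "chemo_contingency": {"table": table.tolist(),
                                  "chi_square": cont.chi_square, "p": cont.p,
                                  "row_proportions": cont.row_proportions.tolist()},
            "roc_auc_resistance": {"auc": roc.auc, "ci": list(roc.ci),
                                   "n_boot": roc.n_boot},
        }
        return km_table, summary

    km_table, summary = _evaluate()
    km_table.to_csv(outdir / "km_curves.csv", index=False, float_format="%.10g")
    (outdir / "evaluation.json").write_text(json.dumps(summary, indent=1))
    artifacts["evaluate"] = str(outdir / "evaluation.json")

    thresholds = {k: cfg[k] for k in sorted(cfg)}
    (outdir / "thresholds_used.json").write_text(json.dumps(thresholds, indent=1))
    artifacts["thresholds"] = str(outdir / "thresholds_used.json")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
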