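"""Seeded study-condition scenarios used for calibration and recovery checks.

Each function simulates the default synthetic study at a stated size and
measures how well the analysis recovers the planted structure: null
calibration of the per-gene test and the set Z-score, recovery of focal
miRNA-target sets, the MIR-versus-TFT correlation contrast, classifier
recovery of the latent subtype, and the clinical endpoint analogue.  They are
the single source for both the test suite and the reporting script; every
random quantity is driven by the seed argument alone.
"""

from __future__ import annotations

import numpy as np

from . import bccp, clinical, diffexp, gsa, simulate

ORIENTATIONS = ("high", "high", "high", "low")


def _run_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)]


def null_calibration(seed: int, n_genes: int = 10_000, n_sets: int = 2000,
                     set_size: int = 50) -> dict:
    """A delta=0 experiment (3 vs 3): fraction of genes at p < 0.05 and the
    mean/sd of Z-scores of randomly drawn gene sets."""
    s1, s2 = _run_seeds(seed, 2)
    design = simulate.ExperimentDesign(conditions={"t": "high", "r": "low"},
                                       n_genes=n_genes, seed=s1)
    matrix, _ = simulate.generate_experiment(design)
    res = diffexp.contrast(matrix, "t", "r")
    coll = simulate.random_collection("RAND", n_sets, set_size,
                                      matrix.gene_ids, seed=s2)
    prof = gsa.profile_collection(res, coll)
    return {
        "p_fraction": float((res.p < 0.05).mean()),
        "z_mean": float(prof.z.mean()),
        "z_sd": float(prof.z.std(ddof=1)),
        "n_genes": n_genes,
        "n_sets": n_sets,
    }


def _study_profiles(seed: int, collection, focal, orientation, label):
    design = simulate.study_experiment(collection, focal,
                                       orientation=orientation,
                                       seed=seed, label=label)
    matrix, _ = simulate.generate_experiment(design)
    return diffexp.contrast(matrix, f"{label}_treated", f"{label}_control",
                            name=label)


def mir_recovery(seed: int, n_runs: int = 100, n_sets: int = 200,
                 set_size: int = 50, n_focal: int = 5,
                 n_genes: int = 10_000) -> dict:
    """Four-experiment panels (three nc886-high inductions, one knockdown)
    with planted focal MIR sets; measures how often the focal sets occupy the
    top summed oriented ranks and how often the nc886-high profile shows an
    enriched majority."""
    top = 0
    enriched_majority = 0
    for k, run_seed in enumerate(_run_seeds(seed, n_runs)):
        sub = _run_seeds(run_seed, 5)
        genes = simulate.default_gene_ids(n_genes)
        coll = simulate.random_collection("MIR", n_sets, set_size, genes,
                                          seed=sub[0])
        focal = list(coll.sets)[:n_focal]
        profiles = []
        for e, orient in enumerate(ORIENTATIONS):
            res = _study_profiles(sub[1 + e], coll, focal, orient, f"e{e}")
            profiles.append(gsa.profile_collection(res, coll))
        orient_signs = [1 if o == "high" else -1 for o in ORIENTATIONS]
        ranked = gsa.rank_mirs(profiles, orient_signs)
        top += {name for name, _ in ranked[:n_focal]} == set(focal)
        dist = gsa.rank_distribution(profiles[0])
        enriched_majority += dist.n_enriched > dist.n_depleted
    return {
        "top_rank_recovery_rate": top / n_runs,
        "enriched_majority_rate": enriched_majority / n_runs,
        "n_runs": n_runs,
    }


def mir_vs_tft(seed: int, n_runs: int = 100, n_sets: int = 200,
               set_size: int = 50, n_focal: int = 5,
               n_genes: int = 10_000) -> dict:
    """Paired nc886-high experiments with MIR structure planted and TFT sets
    left null: how often the MIR profile correlation is the stronger one."""
    wins = 0
    r_mir_all, r_tft_all = [], []
    for run_seed in _run_seeds(seed + 1, n_runs):
        sub = _run_seeds(run_seed, 4)
        genes = simulate.default_gene_ids(n_genes)
        mir = simulate.random_collection("MIR", n_sets, set_size, genes,
                                         seed=sub[0])
        tft = simulate.random_collection("TFT", n_sets, set_size, genes,
                                         seed=sub[1])
        focal = list(mir.sets)[:n_focal]
        contrasts = [_study_profiles(sub[2 + e], mir, focal, "high", f"e{e}")
                     for e in range(2)]
        r_mir = gsa.compare_profiles(
            gsa.profile_collection(contrasts[0], mir),
            gsa.profile_collection(contrasts[1], mir)).pearson_r
        r_tft = gsa.compare_profiles(
            gsa.profile_collection(contrasts[0], tft),
            gsa.profile_collection(contrasts[1], tft)).pearson_r
        r_mir_all.append(r_mir)
        r_tft_all.append(r_tft)
        wins += abs(r_mir) > abs(r_tft)
    return {
        "mir_stronger_rate": wins / n_runs,
        "mean_abs_r_mir": float(np.mean(np.abs(r_mir_all))),
        "mean_abs_r_tft": float(np.mean(np.abs(r_tft_all))),
        "n_runs": n_runs,
    }


def loocv_separable(seed: int, n_runs: int = 100, n_per_class: int = 6,
                    n_genes: int = 50, shift: float = 1.5,
                    noise_sd: float = 0.5) -> dict:
    """LOOCV on well-separated classes (class shift 3x the noise sd)."""
    zero = 0
    rates = []
    for run_seed in _run_seeds(seed + 2, n_runs):
        rng = np.random.default_rng(run_seed)
        values = rng.normal(8, noise_sd, size=(n_genes, 2 * n_per_class))
        values[:, :n_per_class] += shift
        from .io import ExpressionMatrix
        samples = [f"s{i}" for i in range(2 * n_per_class)]
        cond = {s: ("high" if i < n_per_class else "low")
                for i, s in enumerate(samples)}
        m = ExpressionMatrix([f"g{i}" for i in range(n_genes)], samples,
                             values, cond)
        rate, _ = bccp.loocv(m, cond, m.gene_ids)
        rates.append(rate)
        zero += rate == 0
    return {"zero_error_rate": zero / n_runs,
            "mean_loocv_error": float(np.mean(rates)), "n_runs": n_runs}


def cohort_recovery(seed: int, n_patients: int = 285,
                    n_signature: int = 118, n_genes: int = 500,
                    delta_sig: float = 1.0, noise_sd: float = 0.5) -> dict:
    """Train on a designed panel, classify a simulated cohort, and score
    agreement of determined labels with the planted subtype."""
    s1, s2 = _run_seeds(seed + 3, 2)
    design = simulate.CohortDesign(
        n_patients=n_patients, n_genes=n_genes, n_signature_genes=n_signature,
        delta_sig=delta_sig, noise_sd=noise_sd, seed=s1)
    panel, labels = simulate.generate_labeled_panel(design, 12, 9, seed=s2)
    model = bccp.fit(panel, labels, design.signature_genes)
    cohort, _, truth = simulate.generate_cohort(design)
    res = bccp.classify_cohort(model, cohort)
    det = res.table[res.table["label"] != bccp.UNDETERMINED]
    agree = float((det["label"] == det["patient"].map(truth["subtype"])).mean())
    return {
        "agreement": agree,
        "undetermined_fraction": float(
            (res.table["label"] == bccp.UNDETERMINED).mean()),
        "n_patients": n_patients,
    }


def _one_clinical_run(run_seed: int, hazard_ratio: float,
                      p_resistant_high: float, p_resistant_low: float,
                      n_patients: int, n_signature: int, n_genes: int,
                      with_auc: bool) -> tuple[float, float | None]:
    s1, s2 = _run_seeds(run_seed, 2)
    design = simulate.CohortDesign(
        n_patients=n_patients, n_genes=n_genes, n_signature_genes=n_signature,
        delta_sig=1.0, noise_sd=0.5, hazard_ratio=hazard_ratio,
        censoring_rate=0.3, p_resistant_high=p_resistant_high,
        p_resistant_low=p_resistant_low, seed=s1)
    panel, labels = simulate.generate_labeled_panel(design, 12, 9, seed=s2)
    model = bccp.fit(panel, labels, design.signature_genes)
    cohort, clin, _ = simulate.generate_cohort(design)
    res = bccp.classify_cohort(model, cohort)
    merged = res.table.merge(clin.table, left_on="patient",
                             right_on="patient_id")
    det = merged[merged["label"] != bccp.UNDETERMINED]
    hi = det[det["label"] == bccp.HIGH]
    lo = det[det["label"] == bccp.LOW]
    _, p = clinical.logrank((hi["os_time"], hi["os_event"]),
                            (lo["os_time"], lo["os_event"]))
    auc = None
    if with_auc:
        known = merged[merged["chemo_response"] != "unknown"]
        auc = clinical.roc_auc(
            known["p_high"].values,
            known["chemo_response"].eq("resistant").astype(int).values,
            n_boot=20, seed=s2).auc
    return p, auc


def clinical_analogue(seed: int, n_runs: int = 100, n_null_runs: int = 500,
                      n_patients: int = 285, hazard_ratio: float = 3.0,
                      p_resistant_high: float = 0.15,
                      p_resistant_low: float = 0.02) -> dict:
    """Log-rank power and resistance AUC under the alternative
    (hazard ratio 3, subtype-dependent resistance) and log-rank calibration
    under the null (hazard ratio 1, equal resistance)."""
    sig_p, aucs = [], []
    for run_seed in _run_seeds(seed + 4, n_runs):
        p, auc = _one_clinical_run(run_seed, hazard_ratio, p_resistant_high,
                                   p_resistant_low, n_patients,
                                   n_signature=118, n_genes=300, with_auc=True)
        sig_p.append(p)
        aucs.append(auc)
    null_reject = 0
    p_any = (p_resistant_high + p_resistant_low) / 2
    for run_seed in _run_seeds(seed + 5, n_null_runs):
        p, _ = _one_clinical_run(run_seed, 1.0, p_any, p_any, n_patients,
                                 n_signature=50, n_genes=60, with_auc=False)
        null_reject += p < 0.05
    return {
        "logrank_power": float(np.mean(np.asarray(sig_p) < 0.05)),
        "mean_resistance_auc": float(np.mean(aucs)),
        "null_rejection_rate": null_reject / n_null_runs,
        "n_runs": n_runs,
        "n_null_runs": n_null_runs,
    }
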