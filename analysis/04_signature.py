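"""Derive the expression signature: divergent genes, the fold-change
signature rule, two-way clustering, and candidate miRNA target genes.

The signature rule keeps genes with |oriented log2 fc| >= log2(1.3) in at
least 3 of the 4 experiments with a consistent sign; clustering of divergent
genes should split the panel samples into nc886-low and nc886-high groups.
"""

from collections import Counter

from common import build_study, write_json
from mirsig import signature

cfg, mir, tft, focal, panel, contrasts, orientations = build_study()

sig = signature.signature_genes(
    list(contrasts.values()), orientations,
    fold_threshold=cfg["signature_fold"],
    min_experiments=cfg["signature_min_experiments"])
focal_genes = set()
for s in focal:
    focal_genes.update(mir.sets[s])
in_focal = sum(g.upper() in focal_genes for g in sig.genes)
print(f"Signature: {len(sig.genes)} genes pass "
      f"|fc| >= {cfg['signature_fold']}-fold in >= "
      f"{cfg['signature_min_experiments']} oriented experiments; "
      f"{in_focal} are focal-set members.")

condition_groups = sorted(set(panel.sample_condition.values()))
divergent = signature.divergent_genes(
    panel, condition_groups, fold_threshold=cfg["divergent_fold"],
    min_experiments=cfg["divergent_min_experiments"])
print(f"Divergent genes (>= {cfg['divergent_fold']}-fold from the median in "
      f">= {cfg['divergent_min_experiments']} condition group): "
      f"{len(divergent)}")

clust = signature.hierarchical_cluster(panel, divergent)
# score the 2-group sample cut against each sample's nc886 orientation
orient_of = {}
for label, orient in zip(contrasts, orientations):
    for cond, is_high in ((f"{label}_treated", orient == 1),
                          (f"{label}_control", orient != 1)):
        for s in panel.sample_ids:
            if panel.sample_condition[s] == cond:
                orient_of[s] = "high" if is_high else "low"
tab = Counter((clust.sample_partition[s], orient_of[s])
              for s in panel.sample_ids)
agree = max(tab[(1, "high")] + tab[(2, "low")],
            tab[(2, "high")] + tab[(1, "low")]) / panel.n_samples
print(f"Two-group sample cut vs nc886 orientation: {agree:.0%} agreement "
      f"over {panel.n_samples} samples")

targets = signature.candidate_targets(
    contrasts["kd_ose80pc"], contrasts["tgfb_skov3"],
    {s: mir.sets[s] for s in focal}, p_cut=cfg["p_cut"])
print(f"Candidate target genes (down in kd, up under TGF-beta, member of a "
      f"focal set): {len(targets)}")

path = write_json("04_signature.json", {
    "n_signature_genes": len(sig.genes),
    "n_signature_in_focal_sets": in_focal,
    "n_divergent_genes": len(divergent),
    "cluster_orientation_agreement": agree,
    "n_candidate_targets": len(targets),
    "signature_genes": sig.genes,
})
print(f"Wrote {path}")
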