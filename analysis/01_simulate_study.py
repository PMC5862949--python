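"""Simulate the synthetic study panel and report what was planted.

Generates one array panel of four replicated experiments (shared per-gene
baselines, as on one platform) and summarizes the planted structure: every
MIR-set member gene carries a weak +0.15 log2 shift in the nc886-high
condition and the five focal sets an extra +0.35 (total +0.5), emulating
pathway-wide miRNA suppression with a handful of strongly affected miRNAs.
"""

from common import build_study, write_json

cfg, mir, tft, focal, panel, contrasts, orientations = build_study()

union = mir.union()
print(f"Simulated a panel of {len(contrasts)} experiments, "
      f"{cfg['replicates']}+{cfg['replicates']} replicates each "
      f"({panel.n_samples} samples), {cfg['n_genes']} genes.")
print(f"MIR collection: {len(mir)} sets of {cfg['set_size']} genes "
      f"({len(union)} genes in the union, all shifted "
      f"+{cfg['background_shift']} log2 when nc886 is high).")
print(f"TFT collection: {len(tft)} sets (no planted structure).")
print(f"Focal sets ({len(focal)}): total shift "
      f"+{cfg['background_shift'] + cfg['focal_extra_shift']} log2.")
for label, orient in zip(contrasts, orientations):
    side = "nc886-high" if orient == 1 else "nc886-low (knockdown)"
    print(f"  {label}: treated condition is {side}")

path = write_json("01_study_summary.json", {
    "n_genes": cfg["n_genes"],
    "n_samples": panel.n_samples,
    "experiments": list(contrasts),
    "orientations": orientations,
    "focal_sets": focal,
    "n_mir_sets": len(mir), "n_tft_sets": len(tft),
    "mir_union_size": len(union),
})
print(f"Wrote {path}")
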