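"""Per-experiment differential expression, set intersections, and
cross-experiment fold-change correlation.

Applies the p < 0.05 plus |log2 fc| >= 0.5 selection to every contrast,
intersects the altered-gene lists of the two SKOV3-style experiments, and
correlates fold changes of genes jointly significant in each experiment pair
(no fc cutoff), expecting positive r between like-oriented experiments and
negative r against the knockdown.
"""

from itertools import combinations

from common import build_study, write_json
from mirsig import diffexp

cfg, mir, tft, focal, panel, contrasts, orientations = build_study()

selected = {}
for label, res in contrasts.items():
    selected[label] = diffexp.select_significant(
        res, cfg["p_cut"], cfg["fc_cut"])
    print(f"{label}: {len(selected[label])} genes altered "
          f"(p < {cfg['p_cut']}, |fc| >= {cfg['fc_cut']})")

a, b = "tgfb_skov3", "nc886_skov3"
only_a, both, only_b = diffexp.venn(selected[a], selected[b])
print(f"Venn {a} vs {b}: {only_a} | {both} | {only_b} "
      f"({both}/{only_b + both} of the {b} genes are shared)")

correlations = {}
for x, y in combinations(contrasts, 2):
    rep = diffexp.correlate_contrasts(contrasts[x], contrasts[y],
                                      p_cut=cfg["p_cut"])
    correlations[f"{x}__{y}"] = {"r": rep.pearson_r, "p": rep.p_value,
                                 "n_genes": rep.gene_count}
    print(f"  fc correlation {x} vs {y}: r = {rep.pearson_r:+.4f} "
          f"over {rep.gene_count} jointly significant genes (p = {rep.p_value:.3g})")

path = write_json("02_differential_expression.json", {
    "selected_counts": {k: len(v) for k, v in selected.items()},
    "venn_tgfb_vs_nc886": [only_a, both, only_b],
    "fc_correlations": correlations,
})
print(f"Wrote {path}")
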