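# mirsig

Inference of miRNA-pathway activity from bulk expression data, and
classification of patients by an expression signature — the analysis chain
behind studies of nc886, a Pol III non-coding RNA that is induced by TGF-β,
inhibits Dicer, and thereby suppresses miRNA maturation in ovarian cancer.
When the miRNA pathway is suppressed, the target genes of many miRNAs are
collectively de-repressed; this package quantifies that footprint in
expression contrasts, derives a gene signature of the nc886-high state, and
uses it to stratify a patient cohort by survival and chemo-resistance.

It is organized as an analysis project: the computation lives in the library
under `src/mirsig/`, the numbered scripts under `analysis/` walk through the
study stage by stage, and a synthetic-data generator with planted ground
truth makes every stage verifiable at desk scale.

## The statistics at the core

**Per-gene contrasts.** For a replicated two-condition comparison, each gene
gets a log2 fold change fc = mean(log2 treatment) − mean(log2 reference) and a
pooled-variance Student t with n₁+n₂−2 df (two-sided p). Altered genes are
selected by p < 0.05 and |fc| ≥ 0.5.

**Gene-set activity Z-score (PAGE-style).** For a set with m member genes
matched in the contrast,

    z = (S_m − μ) · √m / σ

where S_m is the mean member fold change and μ, σ the mean and standard
deviation of all fold changes. Under a null contrast z ≈ N(0, 1). For a
miRNA-target (MIR) set, z > 0 means the targets are collectively elevated,
i.e. the corresponding miRNA activity is low. Sorting a collection's Z-scores
ascending gives a rank distribution whose x-intercept splits depleted from
enriched sets; transcription-factor-target (TFT) sets serve as the contrast
collection.

**Signature and classifier.** Signature genes have |oriented fc| ≥ log2(1.3)
in ≥ 3 experiments with a consistent sign. The Bayesian Compound Covariate
Predictor (BCCP) weights each signature gene by its two-class t statistic
t_i on standardized training values and reduces a sample to the compound
covariate c = Σ t_i x_i; the two classes induce Gaussians N(m_high, s²),
N(m_low, s²) on c and the posterior P(high | c) follows from Bayes' rule.
Patients are called nc886-high if P > 0.7, nc886-low if P < 0.3, and
undetermined otherwise; the training error is estimated by leave-one-out
cross-validation with full re-derivation per fold.

**Clinical evaluation.** Kaplan–Meier curves with the log-rank test, a 2×2
χ² test of chemo response by predicted subtype, and ROC AUC (Mann–Whitney
concordance) of the posterior for predicting resistance, with a stratified
percentile-bootstrap confidence interval.

## Worked example

Running the analysis scripts in order (each is deterministic for the default
seed) reproduces the study's logic on the synthetic panel:

```sh
cd analysis
python 01_simulate_study.py
python 03_geneset_activity.py
```

prints, among other lines:

```
tgfb_skov3 / MIR: 41 depleted, 180 enriched (x-intercept rank 42 of 221)
kd_ose80pc / MIR: 178 depleted, 43 enriched (x-intercept rank 179 of 221)
kd vs TGF-beta MIR Z-scores: r = -0.4107 (p = 2.11e-10), quadrants {'I': 37, 'II': 143, 'III': 35, 'IV': 6, 'axis': 0}
kd vs TGF-beta TFT Z-scores: r = -0.1434 (p = 0.00036), ...
Top 5 MIR sets by summed oriented Z (all focal): ...
```

Read: in the nc886-high condition the large majority of the 221 MIR sets are
enriched (miRNA activity low); knockdown shows the mirror image; the
kd-versus-induction correlation is strong and negative for MIR sets but weak
for TFT sets, and the five truly planted sets top the summed oriented
ranking. Continuing with `04` – `06` derives the signature, trains the BCCP
(LOOCV error 0.000), classifies the 285-patient synthetic cohort, and prints

```
OS: log-rank chi2 = 53.5, p = 2.59e-13; 24-month survival 23% (high) vs 65% (low)
Chemo resistance: 23 of 24 resistant patients (96%) are nc886-high; chi2 = 24.7, p = 6.73e-07
ROC for resistance from the posterior: AUC = 76.5% (95% bootstrap CI 70.8%-80.8%, 2000 resamples)
```

`mirsig.run_pipeline(config, outdir)` chains all stages from one flat config
(see `mirsig.config.default_config()`) and writes per-stage CSV/JSON
artifacts plus a log of every threshold used.

Real data drop in at the same interfaces: `read_expression` (TSV genes ×
samples plus a sample-annotation table), `read_gmt` (MSigDB collections) and
`read_clinical` (CSV).

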