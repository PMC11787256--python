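# evpdiet

Maternal diet quality and the miRNA cargo of circulating extracellular
vesicles and particles (EVPs): a tested, reusable analysis pipeline for
small pregnancy-cohort studies pairing a food-frequency-derived diet
index with NanoString nCounter miRNA panels.

The package is aimed at epidemiologists and molecular-biology analysts
who have (a) an intake table suitable for Alternative Healthy Eating
Index 2010 (AHEI-2010) scoring, (b) a raw probe x sample count matrix
with positive- and negative-control probes, and (c) a participant
covariate table — or who want to rehearse and validate the full analysis
on realistic synthetic data before touching a real cohort.

## What it computes

**Diet scoring.** AHEI-2010 awards 0–10 points per component across 11
components (total 0–110). Linearly-anchored components interpolate
between an intake scoring 0 and an intake scoring 10 (reverse-coded for
red/processed meat, sugar-sweetened beverages, trans fat); sodium is
scored by cohort deciles; alcohol is J-shaped (0 drinks/day → 2.5,
moderate window → 10, ≥ 2.5 drinks/day → 0).

**Count processing.** Counts are rescaled per sample so positive-control
geometric means agree across samples; each sample's limit of detection
(LOD) is `mean + 1.5·SD` of its negative-control probes; a probe is
detected when its normalized count exceeds the LOD.

**Composition summaries.** Per sample: total normalized endogenous
counts (log2 for modeling); richness `s` = number of detected probes;
evenness = normalized Shannon entropy of detected relative abundances,

```
evenness = (-Σᵢ pᵢ ln pᵢ) / ln(s),   pᵢ = countᵢ / Σ detected counts,
```

bounded in [0, 1] and undefined for s ≤ 1.

**Association models.** Huber M-estimation robust linear regression
(IRLS, tuning constant c = 1.345, MAD scale, H1 covariance, t(n−p)
inference) of each composition outcome on the total AHEI score, adjusted
for education, vigorous physical activity, and blood-draw time; ten
component-score exposures with additional caloric-intake adjustment;
per-miRNA post hoc models stratified by detection rate (>60% detected:
robust linear on log2 counts; 20–60%: detection logistic; <20%:
excluded) with Benjamini–Hochberg and Bonferroni control; six
sensitivity re-fits; a hypergeometric overrepresentation test for
target-gene sets.

**Synthetic cohorts.** `evpdiet.simulate` generates covariates, intakes
(through a latent diet-quality factor calibrated to an AHEI mean/SD of
64.7/10.4), and negative-binomial nCounter-like counts with per-sample
lot scale factors, logistic expressed-vs-silent indicators (richness
mean ≈ 192), and configurable diet–miRNA effects planted on named
probes — so every downstream stage can be checked against generating
truth.

## Worked example

```
evpdiet run-all --out-dir results/demo --seed 3
```

simulates the default 53-participant cohort (798 endogenous + 6
positive + 8 negative probes), scores it, normalizes counts, summarizes
composition, fits every association stage, and renders `report.md`.
With seed 3, `results/demo/table2.csv` contains:

```
outcome,effect (95% CI),p
log2_total,"-0.023 (-0.038, -0.008)",0.0031
richness,"-2.714 (-4.618, -0.810)",0.0061
evenness,"0.000 (-0.000, 0.001)",0.3355
```

Read: each additional AHEI-2010 point is associated with ≈ 2.7 fewer
unique miRNA transcripts detected per sample (95% CI −4.6 to −0.8) —
the default generator plants a richness effect of −3 transcripts per
point, and the fitted CI covers it — while evenness shows no
association. The run directory also holds the cohort summary
(`table1.csv`), the component-score forest plot, per-miRNA volcano
plots, and a `manifest.json` recording the seed and configuration hash;
re-running with the same seed reproduces every table byte-for-byte.

Each stage is also exposed separately (`evpdiet simulate | score-ahei |
normalize | compose | associate | enrich | report`) and as plain library
functions / sklearn-style estimators (`AHEIScorer`,
`PositiveControlNormalizer`, `DetectionCaller`, `HuberRegression`,
`DetectionLogistic`).

## Documentation

`docs/methods.md` describes the generating model, the estimators, all
tunable parameters and their defaults, numerical choices, and known
limitations.
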