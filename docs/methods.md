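# Methods

This note documents the models, defaults, and numerical choices behind
`evpdiet`, and what the synthetic-data suites do and do not demonstrate.

## AHEI-2010 scoring

Eleven components, each scored 0–10; the total is their sum (0–110).

| component | unit | score-0 anchor | score-10 anchor | mode |
|---|---|---|---|---|
| vegetables | servings/day | 0 | ≥ 5 | linear |
| fruit | servings/day | 0 | ≥ 4 | linear |
| whole grains | g/day | 0 | ≥ 75 | linear |
| SSB + fruit juice | servings/day | ≥ 1 | 0 | linear (reverse) |
| nuts/legumes/soy | servings/day | 0 | ≥ 1 | linear |
| red/processed meat | servings/day | ≥ 1.5 | 0 | linear (reverse) |
| trans fat | % energy | ≥ 4 | ≤ 0.5 | linear (reverse) |
| EPA + DHA | mg/day | 0 | ≥ 250 | linear |
| PUFA | % energy | ≤ 2 | ≥ 10 | linear |
| sodium | mg/day | highest decile | lowest decile | cohort decile |
| alcohol | drinks/day | — | — | J-shape |

Linear scores are `10·clamp((x − x₀)/(x₁ − x₀), 0, 1)`, which handles
both directions; intakes at or beyond an anchor receive exactly the
extreme score. Whole-grain and alcohol rules use the female anchors
since the intended cohort is pregnant women. The alcohol J-shape maps 0
drinks/day to 2.5, ramps linearly to 10 at 0.5 drinks/day, holds 10
through 1.5 (the female moderate window — the window bounds are a design
choice, configurable), and falls linearly to 0 at 2.5 drinks/day.
Sodium deciles are computed within the scored cohort with average-rank
tie handling; decile k ∈ {0..9} maps to `10·k/9`, reversed. Cohorts
under 10 participants, or constant sodium, degenerate to a uniform score
of 5 with a warning. All anchors are overridable from a YAML file.

A note on PUFA: a cohort whose median PUFA score equals its median
%-energy value is internally inconsistent with the standard ≤2%→0 /
≥10%→10 anchors (6.94% energy scores 6.175, not 6.94). The
implementation keeps the standard anchors and does not force the score
to equal %-energy.

## NanoString processing

* **Normalization.** Per-sample factor
  `f_j = mean_k[geomean(pos_k)] / geomean(pos_j)` applied to all probes —
  the standard geometric-mean positive-control (code-count) correction.
  Zero positive-control counts raise an error by default (configurable
  +0.5 floor). Re-application is the identity. Because the grand mean
  moves with the samples, rescaling one raw sample leaves the normalized
  matrix unchanged only up to a single global constant; all downstream
  statistics are invariant to that constant (log2 totals shift equally;
  richness, evenness and slopes are unaffected).
* **LOD.** `mean + m·SD` of each sample's negative-control probes, with
  `m = 1.5` and sample SD (n−1) by default; both configurable. The LOD
  is computed after positive-control normalization (configurable in
  principle via running the steps manually; the pipeline records the
  order in its manifest).
* **Detection.** Strict `count > LOD` by default ("above the
  threshold"); `≥` available. No background subtraction is performed —
  the LOD governs detection only, never count correction.

## Composition summaries

Total counts sum **all** endogenous probes, detected or not; log2 with
no pseudocount (a zero total is treated as a data error and flagged
missing rather than imputed). Richness is the detection-call column
sum. Evenness uses natural logs and the detected probes only; for
s ≤ 1 the value is recorded as missing, not zero.

## Association models

* **Robust linear.** Huber M-estimation by IRLS: ψ-function clamps
  standardized residuals at c = 1.345; scale is `median|r|/0.6745`
  re-estimated each iteration; convergence on maximum relative
  coefficient change < 1e-8, up to 300 iterations (slow, not divergent,
  convergence arises on bimodal log2-count residuals; non-convergence is
  flagged, never silently accepted). Covariance is the Huber "H1"
  asymptotic form with the small-sample correction factor; p-values and
  CIs use t(n−p). The implementation agrees with `statsmodels` RLM to
  1e-7 and with `MASS::rlm` to ~1e-5 on frozen fixtures, and reduces to
  OLS as c → ∞.
* **Detection logistic.** Maximum-likelihood logistic regression (GLM
  IRLS) with Wald normal inference. "Robust logistic regression" has no
  canonical definition in the tradition this plan follows; standard ML
  is used and complete separation (|fitted log-odds| > 20 or
  non-convergence) is flagged in the result row rather than raised, so
  per-miRNA batches can skip and log.
* **Covariates.** Primary: education (binary), vigorous activity
  (hrs/wk), afternoon vs morning draw. Component and per-miRNA models
  with component-score exposures add total caloric intake. Missing data
  are handled complete-case per model with dropped-row counts logged;
  models refuse to fit below 10 complete rows.
* **Strata.** Detection rate < 20%: excluded; 20–60% (both endpoints
  inclusive): binary; > 60%: continuous. Continuous-stratum outcomes are
  `log2(normalized count + 0.5)` over all samples; the pseudocount only
  matters for below-LOD counts and is negligible for the
  comfortably-detected probes the stratum contains.
* **Candidate screen.** "Richness-associated" (or evenness-associated)
  probes are recomputed on the data at hand: each ≥20%-detected probe is
  regressed on the composition measure (by stratum) and retained at
  Bonferroni p < 0.05 across the screen family. The original screen's
  covariate set is unknowable from the outside; the screen here uses
  unadjusted per-probe models, documented as such.
* **Multiple testing.** BH step-up q-values and Bonferroni within the
  family of all per-miRNA tests for one exposure in one run. Own
  implementation (validated against `statsmodels.multipletests`), NaN
  p-values excluded from the family size.
* **Sensitivity variants.** never-smokers, excluding gestational
  diabetes, excluding gestational hypertension, adding pre-pregnancy
  BMI, multivitamin users only, no morning-sickness medication; each
  re-fit reports its n, subsets under 10 rows are skipped with a
  warning.
* **Overrepresentation.** One-sided hypergeometric tail
  `P(overlap ≥ observed)` with pathway sets intersected with the
  background, BH across pathways. Gene sets read from GMT.

## Synthetic-data generator

The generator's defaults encode the study conditions the pipeline is
meant for: 53 participants; binary covariate prevalences 3/53 ever
smokers, 2/53 gestational diabetes, 4/53 gestational hypertension,
51/53 multivitamin users, 8/53 morning-sickness medication, 47/53
college graduates, 26/53 afternoon draws; age ~ N(32.5, 4.0²), BMI ~
N(23.9, 5.0²), kcal/day ~ N(2039.4, 622.3²) truncated at 600, vigorous
activity zero-inflated exponential (P(0)=0.5, mean 1 hr/wk), gestational
age ~ N(28.8, 2.8²). An option emits one missing-activity row to
exercise the complete-case path (the 54-enrolled / 53-analyzed pattern).

**Diet.** A latent quality factor q ~ N(0,1) loads on every component:
each linearly-anchored component score is `clip(m + 0.93·q + 1.82·ε, 0,
10)` with m solved (closed-form clipped-normal mean, Brent root-finding)
so the clipped mean hits its target (nuts 9.4, red/processed meat 5.73,
PUFA 6.94 — the printed cohort medians, treated as means — and plausible
values for the rest). Intakes are obtained by inverting the anchor maps,
so scoring the intake table reproduces the planted scores exactly.
Sodium is log-normal with a −0.12 loading on q; alcohol is 85%
abstainers plus light drinkers (0.02–0.2 drinks/day). The loading/noise
pair (0.93, 1.82) was calibrated once so the total's mean/SD land at
≈ 64.7/10.4; the SD is reported as 10.3 in one place and 10.4 in
another in the motivating cohort — the generator targets 10.4.

**Counts.** Per probe i: baseline log2 mean λᵢ ~ N(·, 1.8²) (floored at
log2 32 so expressed probes clear the LOD), NB size ~ U(5, 20),
detection logit αᵢ ~ N(·, 2²). Per sample j: repertoire random effect
uⱼ ~ N(0, 0.75²) and lot scale factor cⱼ ~ logN(0, 0.15²). Probe i is
expressed in sample j with probability `sigmoid(αᵢ + uⱼ + γ·(AHEIⱼ −
mean))`; expressed probes draw NB counts with mean `cⱼ·2^{λᵢ + βᵢ(eⱼ −
ē)}` (βᵢ the planted log2 slope for effect targets, e the configured
exposure), silent probes draw Poisson background (mean 2·cⱼ); negative
controls are Poisson(6·cⱼ); positive controls follow a Poisson
concentration ladder (30000 … 300)·cⱼ. The ladder spans two decades
rather than the platform's six so that the 6-probe geometric mean
estimates the lot factor with ≈ 1% noise; per-sample normalization
error is therefore ~1% on average, and the invertibility check is
stated on the mean relative error. Intercepts are calibrated
deterministically (Gauss–Hermite expectations + Brent) so expected
richness and expected total counts hit their targets (defaults 191.7
and 18756.6; realized evenness ≈ 0.87, richness SD ≈ 75).

**Planted effects.** The richness effect is specified in transcripts
per AHEI point and converted to the shared logit slope via
`γ = slope / Σᵢ E[pᵢ(1−pᵢ)]`, the derivative of expected richness
averaged over the sample random effect; the default is −3 transcripts
per point, the direction and size of the motivating cohort's headline
estimate. Per-miRNA targets are by default pinned to high expression
propensity (≥ 0.95) and a detectable baseline so the planted slope is
measurable in the continuous stratum. A single global seed feeds
per-stage `SeedSequence` spawn keys, so reconfiguring a later stage
never perturbs earlier draws.

**What the generator does not emulate:** RCC-level artifacts
(ligation/hybridization chemistry), probe cross-hybridization,
correlation between a probe's abundance and its detection propensity
beyond the shared sample effect, covariate–diet dependence (education
and activity are independent of q), and batch structure. Passing
recovery and calibration suites therefore demonstrates correctness of
the estimators under the stated generating model, not robustness to
those real-data features.

## Simulation suite sizes

Null calibration: 200 replicates at n = 100 on a 160-probe panel
(calibration of test level is panel-size independent). Richness-slope
recovery: 200 replicates at n = 500 on the full 798-probe panel.
Per-miRNA recovery and FDR flagging: 200 replicates at n = 500 on the
160-probe panel with seven planted targets at −0.105 log2 per
meat-score point; candidate sets passed explicitly as all ≥20%-detected
probes (the screen is exercised separately and in the end-to-end
pipeline). These sizes keep each suite in the tens-of-seconds to
minutes range on one CPU.

## Known limitations

* Evenness is bounded and mildly heteroscedastic; robust linear
  regression on it is the analysis plan's choice, not an optimal model.
* The per-sample repertoire effect uⱼ makes richness overdispersed
  relative to a pure logistic model; the planted-slope conversion
  corrects the mean derivative but a few percent attenuation remains
  from detection error around the LOD (measured ≈ 1–3%, inside the
  recovery tolerance).
* The H1 covariance/t(n−p) convention is one of several defensible
  inference choices for M-estimators; the reference used by the
  original analysis tooling is not stated anywhere, so agreement is
  verified against MASS/statsmodels conventions instead.
* Decile scoring of new samples against a fitted cohort pools the new
  intakes with the reference cohort; alternative conventions (frozen
  decile edges) would differ at the margins.
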