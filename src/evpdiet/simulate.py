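"""Synthetic cohort and NanoString-style count generation.

Emulates a small pregnancy-cohort study: a food-frequency-derived intake
table feeding the AHEI-2010 score, participant covariates, and a raw
nCounter-like miRNA count matrix (798 endogenous probes plus synthetic
positive/negative controls) with configurable diet-miRNA effects planted
on known probes, so every downstream stage can be validated against the
generating truth.

Generating model
----------------
* A latent diet-quality factor q ~ N(0,1) drives all component scores:
  each linearly-anchored component score is a clipped normal
  ``clip(m + a q + b eps, 0, 10)`` whose latent mean m is solved so the
  clipped mean hits the component's target; intakes are recovered by
  inverting the anchor map, so scoring the intake table reproduces the
  planted scores exactly.  Sodium is log-normal (decile-scored within the
  cohort) and alcohol a zero-inflated light-drinking mixture.
* Counts: each endogenous probe i carries a Bernoulli "expressed"
  indicator with logit ``alpha_i + u_j + gamma (AHEI_j - mean)`` (u_j a
  per-sample repertoire-size random effect); expressed probes draw
  negative-binomial counts with log2-mean ``lambda_i + beta_i (e_j -
  mean)`` for effect-target probes, silent probes draw low-mean Poisson
  background.  A per-sample lot scale factor multiplies every probe's
  mean, and positive controls follow a fixed concentration ladder so
  positive-control normalization can undo it.
* The richness effect is specified in transcripts per AHEI point and
  converted internally to a logit slope via the panel's mean Bernoulli
  variance, so the planted value is the slope an analyst should recover
  from measured richness.

All randomness flows from one seed through per-stage ``SeedSequence``
spawn keys, so enabling or reconfiguring a later stage never perturbs an
earlier stage's draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import ahei
from .countmatrix import CountMatrix

__all__ = [
    "CohortConfig",
    "PanelSpec",
    "EffectSpec",
    "generate_cohort",
    "generate_counts",
    "write_fixture_bundle",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

#: Default binary-covariate prevalences for a 53-participant cohort
#: (3 ever-smokers, 2 gestational diabetes, 4 gestational hypertension,
#: 51 multivitamin users, 8 on morning-sickness medication, 47 college
#: graduates, 26 afternoon blood draws, 30 female infants).
_DEFAULT_PREVALENCE = {
    "ever_smoker": 3 / 53,
    "gdm": 2 / 53,
    "ghtn": 4 / 53,
    "multivitamin": 51 / 53,
    "nausea_med": 8 / 53,
    "college_grad": 47 / 53,
    "afternoon_draw": 26 / 53,
    "infant_female": 30 / 53,
}

#: Per-component score calibration: target mean on the 0-10 scale,
#: loading on the shared diet-quality factor, independent noise SD.
#: Targets follow the cohort's printed component medians where available
#: (nuts 9.4, red/processed meat 5.73, PUFA 6.94); loadings/noise are
#: calibrated so the total score SD lands near 10.4.
_DEFAULT_COMPONENT_CALIBRATION = {
    "vegetables": (5.5, 0.93, 1.82),
    "fruit": (6.0, 0.93, 1.82),
    "whole_grains": (4.5, 0.93, 1.82),
    "ssb_fruit_juice": (7.5, 0.93, 1.82),
    "nuts_legumes_soy": (9.4, 0.93, 1.82),
    "red_processed_meat": (5.73, 0.93, 1.82),
    "trans_fat": (8.0, 0.93, 1.82),
    "epa_dha": (3.4, 0.93, 1.82),
    "pufa": (6.94, 0.93, 1.82),
}


@dataclass
class CohortConfig:
    """Cohort size, covariate marginals and diet-score calibration."""

    n_participants: int = 53
    seed: int = 0
    prevalence: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    age_mean: float = 32.5
    age_sd: float = 4.0
    bmi_mean: float = 23.9
    bmi_sd: float = 5.0
    kcal_mean: float = 2039.4
    kcal_sd: float = 622.3
    activity_p_zero: float = 0.5
    activity_mean_hrs: float = 1.0
    gestage_mean: float = 28.8
    gestage_sd: float = 2.8
    n_missing_activity: int = 0
    component_calibration: dict = field(
        default_factory=lambda: dict(_DEFAULT_COMPONENT_CALIBRATION)
    )
    sodium_median_mg: float = 2800.0
    sodium_log_sd: float = 0.30
    sodium_q_loading: float = -0.12
    alcohol_p_drinker: float = 0.15
    alcohol_drinks_range: tuple = (0.02, 0.2)

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        for name, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"prevalence {name!r}={p} outside [0, 1]")
        if not (0.0 <= self.activity_p_zero <= 1.0):
            raise ConfigurationError("activity_p_zero outside [0, 1]")
        finite = [self.age_mean, self.age_sd, self.bmi_mean, self.bmi_sd,
                  self.kcal_mean, self.kcal_sd, self.gestage_mean, self.gestage_sd,
                  self.sodium_median_mg, self.sodium_log_sd]
        if not np.isfinite(finite).all():
            raise ConfigurationError("distribution parameters must be finite")
        if self.n_missing_activity < 0 or self.n_missing_activity > self.n_participants:
            raise ConfigurationError("n_missing_activity outside [0, n_participants]")


@dataclass
class PanelSpec:
    """nCounter-like probe panel and its count law."""

    n_endogenous: int = 798
    n_positive: int = 6
    n_negative: int = 8
    #: spread of per-probe baseline log2 means around the calibrated center
    baseline_log2_sd: float = 1.8
    #: floor on expressed-probe log2 mean (keeps expressed probes above LOD)
    baseline_log2_min: float = 5.0
    #: NB size (inverse-dispersion) range, drawn uniformly per probe
    size_range: tuple = (5.0, 20.0)
    #: spread of per-probe detection-propensity logits
    detection_logit_sd: float = 2.0
    #: SD of the per-sample repertoire random effect on the logit scale
    sample_logit_sd: float = 0.75
    #: Poisson mean of silent-probe background counts (pre scale factor)
    background_mean: float = 2.0
    #: Poisson mean of negative-control probes (pre scale factor)
    negative_mean: float = 6.0
    #: positive-control concentration ladder (expected counts, top down)
    positive_means: tuple = (30000.0, 12000.0, 4800.0, 1900.0, 760.0, 300.0)
    #: log-SD of the per-sample lot scale factor
    scale_log_sd: float = 0.15
    #: calibration targets: expected richness and expected total counts
    target_mean_richness: float = 191.7
    target_total_counts: float = 18756.6

    def __post_init__(self):
        if self.n_endogenous < 1:
            raise ConfigurationError("n_endogenous must be >= 1")
        if self.n_positive < 1 or self.n_negative < 2:
            raise ConfigurationError("need >= 1 positive and >= 2 negative controls")
        if len(self.positive_means) != self.n_positive:
            raise ConfigurationError("positive_means length must equal n_positive")
        if min(self.size_range) <= 0:
            raise ConfigurationError("NB sizes must be > 0")
        if not (0 < self.target_mean_richness <= self.n_endogenous):
            raise ConfigurationError("target_mean_richness outside (0, n_endogenous]")

    @property
    def probe_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_endogenous)]

    @property
    def positive_ids(self) -> list[str]:
        return [f"POS_{chr(ord('A') + i)}" for i in range(self.n_positive)]

    @property
    def negative_ids(self) -> list[str]:
        return [f"NEG_{i + 1:02d}" for i in range(self.n_negative)]


@dataclass
class EffectSpec:
    """Planted diet-miRNA effects.

    ``mirna_log2_slopes`` maps probe id -> slope of log2 expected count
    per unit of ``exposure`` (an AHEI component score or the total).
    ``richness_slope`` is the change in expected number of expressed
    transcripts per point of total AHEI (the headline direction in the
    motivating cohort is negative).  Target probes are by default pinned
    to high expression propensity and a comfortably-detectable baseline
    so the planted slope is measurable.
    """

    exposure: str = "ahei_total"
    mirna_log2_slopes: dict = field(default_factory=dict)
    richness_slope: float = -3.0
    ensure_detectable: bool = True

    def __post_init__(self):
        values = list(self.mirna_log2_slopes.values()) + [self.richness_slope]
        if not np.isfinite(values).all():
            raise ConfigurationError("effect slopes must be finite")

    @classmethod
    def null(cls) -> "EffectSpec":
        """No planted effects anywhere."""
        return cls(mirna_log2_slopes={}, richness_slope=0.0)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage stream from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _clipped_normal_mean(m: float, s: float, lo: float = 0.0, hi: float = 10.0) -> float:
    a, b = (lo - m) / s, (hi - m) / s
    return (lo * norm.cdf(a)
            + hi * norm.sf(b)
            + m * (norm.cdf(b) - norm.cdf(a))
            + s * (norm.pdf(a) - norm.pdf(b)))


def _solve_clipped_mean(target: float, s: float) -> float:
    """Latent mean whose clipped-normal mean equals ``target`` on [0, 10]."""
    if not (0.0 < target < 10.0):
        raise ConfigurationError(f"component score target {target} outside (0, 10)")
    return brentq(lambda m: _clipped_normal_mean(m, s) - target, -40.0, 50.0)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _mean_sigmoid(logits: np.ndarray, sd: float) -> np.ndarray:
    """E[sigmoid(logit + sd Z)] for Z ~ N(0,1), Gauss-Hermite."""
    z = np.sqrt(2.0) * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    grid = logits[:, None] + sd * z[None, :]
    return (w[None, :] / (1.0 + np.exp(-grid))).sum(axis=1)


def _mean_sigmoid_var(logits: np.ndarray, sd: float) -> np.ndarray:
    """E[p(1-p)] with p = sigmoid(logit + sd Z), Z ~ N(0,1)."""
    z = np.sqrt(2.0) * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    p = 1.0 / (1.0 + np.exp(-(logits[:, None] + sd * z[None, :])))
    return (w[None, :] * p * (1.0 - p)).sum(axis=1)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: (covariates table, dietary-intake table).

    Both tables share the participant index; re-running with the same
    config (including its seed) reproduces them exactly.
    """
    n = config.n_participants
    rng_cov = _stage_rng(config.seed, 0)
    rng_diet = _stage_rng(config.seed, 1)
    ids = [f"P{i + 1:03d}" for i in range(n)]

    cov = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    cov["age"] = np.clip(rng_cov.normal(config.age_mean, config.age_sd, n), 18, 50).round(1)
    cov["pre_preg_bmi"] = np.clip(
        rng_cov.normal(config.bmi_mean, config.bmi_sd, n), 15, 55
    ).round(1)
    active = rng_cov.random(n) >= config.activity_p_zero
    cov["vigorous_activity_hrs_wk"] = np.where(
        active, rng_cov.exponential(config.activity_mean_hrs, n), 0.0
    ).round(2)
    cov["gest_age_weeks"] = np.clip(
        rng_cov.normal(config.gestage_mean, config.gestage_sd, n), 20, 40
    ).round(1)
    for name, p in config.prevalence.items():
        cov[name] = (rng_cov.random(n) < p).astype(int)
    if config.n_missing_activity:
        cov.iloc[: config.n_missing_activity,
                 cov.columns.get_loc("vigorous_activity_hrs_wk")] = np.nan

    # ---- diet: latent quality factor -> component scores -> intakes ----
    q = rng_diet.standard_normal(n)
    intakes = pd.DataFrame(index=cov.index)
    by_name = {c.name: c for c in ahei.DEFAULT_COMPONENTS}
    for name, (target, loading, noise) in config.component_calibration.items():
        comp = by_name[name]
        s_total = float(np.hypot(loading, noise))
        m = _solve_clipped_mean(target, s_total)
        score = np.clip(m + loading * q + noise * rng_diet.standard_normal(n), 0.0, 10.0)
        # invert the linear anchor map so scoring reproduces `score`
        intake = comp.intake_at_0 + score / 10.0 * (comp.intake_at_10 - comp.intake_at_0)
        intakes[name] = np.maximum(intake, 0.0)
    # sodium: log-normal, negatively loaded on diet quality (decile-scored)
    log_sodium = (np.log(config.sodium_median_mg)
                  + config.sodium_q_loading * q
                  + config.sodium_log_sd * rng_diet.standard_normal(n))
    intakes["sodium"] = np.exp(log_sodium)
    # alcohol: mostly abstainers (pregnancy), a few light drinkers
    drinker = rng_diet.random(n) < config.alcohol_p_drinker
    lo, hi = config.alcohol_drinks_range
    intakes["alcohol"] = np.where(drinker, rng_diet.uniform(lo, hi, n), 0.0)
    intakes = intakes[list(ahei.COMPONENT_NAMES)]
    intakes["kcal_per_day"] = np.clip(
        rng_diet.normal(config.kcal_mean, config.kcal_sd, n), 600, None
    ).round(1)
    return cov, intakes


# --------------------------------------------------------------------------
# count generation
# --------------------------------------------------------------------------

def generate_counts(
    cohort: tuple[pd.DataFrame, pd.DataFrame] | pd.DataFrame,
    panel: PanelSpec | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
    scale_factors: np.ndarray | None = None,
) -> CountMatrix:
    """Draw a raw probe x sample count matrix for a generated cohort.

    Parameters
    ----------
    cohort : (covariates, intakes) pair from :func:`generate_cohort`
        (or just the intake table; only intakes drive the counts).
    panel, effects : panel law and planted effects (defaults used if None).
    seed : global seed; count draws use their own spawn streams.
    scale_factors : optional explicit per-sample lot scale factors
        (overrides the log-normal draw; useful for invertibility checks).

    Returns a raw :class:`CountMatrix` whose ``meta`` records the
    generating truth (per-probe baselines, propensities, per-sample scale
    factors and exposures) for oracle-style validation.
    """
    panel = panel or PanelSpec()
    effects = effects or EffectSpec()
    if isinstance(cohort, tuple):
        _, intakes = cohort
    else:
        intakes = cohort
    scores = ahei.score_intake_table(intakes[list(ahei.COMPONENT_NAMES)])
    if effects.exposure not in scores.columns:
        raise ConfigurationError(
            f"unknown exposure {effects.exposure!r}; expected an AHEI component "
            "score name or 'ahei_total'"
        )
    unknown = [t for t in effects.mirna_log2_slopes if t not in set(panel.probe_ids)]
    if unknown:
        raise ConfigurationError(f"effect targets not on the panel: {unknown}")

    n = len(intakes)
    rng_panel = _stage_rng(seed, 2)
    rng_counts = _stage_rng(seed, 3)
    n_probes = panel.n_endogenous

    # ---- per-probe panel parameters, calibrated to the targets ----------
    lam = rng_panel.normal(0.0, panel.baseline_log2_sd, n_probes)
    alpha = rng_panel.normal(0.0, panel.detection_logit_sd, n_probes)
    size = rng_panel.uniform(*panel.size_range, n_probes)

    # center detection logits so the expected richness hits the target
    target_p = panel.target_mean_richness / n_probes
    def mean_prop(shift):
        return _mean_sigmoid(alpha + shift, panel.sample_logit_sd).mean() - target_p
    alpha += brentq(mean_prop, -30.0, 30.0)
    pbar = _mean_sigmoid(alpha, panel.sample_logit_sd)

    # center baseline log2 means so the expected endogenous total hits the
    # target; the detectability floor participates in the solve
    silent_total = float(((1.0 - pbar) * panel.background_mean).sum())
    expressed_budget = max(panel.target_total_counts - silent_total, 1.0)

    def floored_total(shift):
        return float(
            (pbar * 2.0 ** np.maximum(lam + shift, panel.baseline_log2_min)).sum()
        ) - expressed_budget

    lam = np.maximum(lam + brentq(floored_total, -40.0, 40.0),
                     panel.baseline_log2_min)

    if effects.ensure_detectable and effects.mirna_log2_slopes:
        idx = {pid: i for i, pid in enumerate(panel.probe_ids)}
        for target in effects.mirna_log2_slopes:
            i = idx[target]
            alpha[i] = max(alpha[i], 3.0)       # propensity >= 0.95
            lam[i] = max(lam[i], np.log2(150))  # comfortably above LOD
        pbar = _mean_sigmoid(alpha, panel.sample_logit_sd)

    # ---- per-sample terms ----------------------------------------------
    ahei_total = scores["ahei_total"].to_numpy()
    exposure = scores[effects.exposure].to_numpy()
    ahei_c = ahei_total - ahei_total.mean()
    expo_c = exposure - exposure.mean()
    u = rng_counts.normal(0.0, panel.sample_logit_sd, n)
    if scale_factors is not None:
        c = np.asarray(scale_factors, dtype=float)
        if c.shape != (n,) or (c <= 0).any():
            raise ConfigurationError("scale_factors must be positive, one per sample")
    else:
        c = np.exp(rng_counts.normal(0.0, panel.scale_log_sd, n))

    # richness slope (transcripts per AHEI point) -> shared logit slope;
    # the derivative of expected richness averages p(1-p) over the
    # per-sample random effect
    bern_var = float(_mean_sigmoid_var(alpha, panel.sample_logit_sd).sum())
    gamma = effects.richness_slope / bern_var if bern_var > 0 else 0.0

    logits = alpha[:, None] + u[None, :] + gamma * ahei_c[None, :]
    expressed = rng_counts.random((n_probes, n)) < 1.0 / (1.0 + np.exp(-logits))

    beta = np.zeros(n_probes)
    for target, slope in effects.mirna_log2_slopes.items():
        beta[panel.probe_ids.index(target)] = slope
    log2_mu = lam[:, None] + beta[:, None] * expo_c[None, :]
    mu = c[None, :] * 2.0 ** log2_mu
    nb_p = size[:, None] / (size[:, None] + mu)
    expressed_counts = rng_counts.negative_binomial(size[:, None], nb_p)
    background = rng_counts.poisson(c[None, :] * panel.background_mean,
                                    (n_probes, n))
    endo = np.where(expressed, expressed_counts, background)

    negatives = rng_counts.poisson(c[None, :] * panel.negative_mean,
                                   (panel.n_negative, n))
    positives = rng_counts.poisson(
        c[None, :] * np.asarray(panel.positive_means)[:, None]
    )

    ids = panel.probe_ids + panel.positive_ids + panel.negative_ids
    classes = (["Endogenous"] * n_probes + ["Positive"] * panel.n_positive
               + ["Negative"] * panel.n_negative)
    counts = pd.DataFrame(
        np.vstack([endo, positives, negatives]),
        index=pd.Index(ids, name="probe_id"),
        columns=intakes.index,
    )
    meta = {
        "baseline_log2_mean": pd.Series(lam, index=panel.probe_ids),
        "detection_logit": pd.Series(alpha, index=panel.probe_ids),
        "expression_propensity": pd.Series(pbar, index=panel.probe_ids),
        "nb_size": pd.Series(size, index=panel.probe_ids),
        "scale_factors_true": pd.Series(c, index=intakes.index),
        "exposure": pd.Series(exposure, index=intakes.index,
                              name=effects.exposure),
        "richness_logit_slope": gamma,
        "seed": seed,
    }
    return CountMatrix(counts=counts,
                       probe_class=pd.Series(classes, index=counts.index),
                       normalized=False, meta=meta)


# --------------------------------------------------------------------------
# fixture bundles
# --------------------------------------------------------------------------

def _config_hash(*configs) -> str:
    def default(o):
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True,
                         default=default)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_fixture_bundle(
    outdir,
    config: CohortConfig | None = None,
    panel: PanelSpec | None = None,
    effects: EffectSpec | None = None,
) -> dict:
    """Write covariates.csv, intakes.csv, counts.csv and a manifest.

    Returns the manifest dict.  Re-running with identical configuration
    produces byte-identical CSV payloads.
    """
    config = config or CohortConfig()
    panel = panel or PanelSpec()
    effects = effects or EffectSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov, intakes = generate_cohort(config)
    counts = generate_counts((cov, intakes), panel, effects, seed=config.seed)
    cov.to_csv(outdir / "covariates.csv")
    intakes.to_csv(outdir / "intakes.csv")
    counts.to_csv(outdir / "counts.csv")
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config, panel, effects),
        "n_participants": int(config.n_participants),
        "n_endogenous": int(panel.n_endogenous),
        "exposure": effects.exposure,
        "files": ["covariates.csv", "intakes.csv", "counts.csv"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
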