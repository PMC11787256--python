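"""Covariate-adjusted association models and multiple-testing control.

The analysis plan mirrors a small diet/EVP-miRNA cohort study:

* Primary: each composition summary (log2 total counts, richness,
  evenness) regressed on the total AHEI-2010 score by Huber robust
  linear regression, adjusted for education, vigorous physical activity
  and blood-draw time of day.
* Secondary: ten AHEI component scores (alcohol excluded) as exposures
  for the significant composition outcome, additionally adjusting for
  total caloric intake.
* Post hoc per-miRNA: probes detected in >60% of samples modeled as
  continuous log2 counts (robust linear); probes detected in 20-60% as
  binary detectable-vs-not (logistic); probes under 20% excluded.
  Benjamini-Hochberg q-values and Bonferroni-adjusted p-values are
  computed within the family of tests for one exposure.
* Sensitivity: six re-fits on defined subsets / augmented covariates.
* A generic hypergeometric overrepresentation test for target-gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .countmatrix import CountMatrix
from .robust import DetectionLogistic, HuberRegression

logger = logging.getLogger(__name__)

__all__ = [
    "PRIMARY_COVARIATES",
    "SECONDARY_COMPONENTS",
    "SENSITIVITY_VARIANTS",
    "ModelSpec",
    "adjust_pvalues",
    "assign_modeling_stratum",
    "fit_robust_linear",
    "fit_detection_logistic",
    "run_primary_analysis",
    "run_component_analysis",
    "screen_composition_associated",
    "run_posthoc_mirna",
    "run_sensitivity",
    "overrepresentation_test",
    "read_gmt",
    "log2_counts",
]

#: Covariates of the primary models: education (binary), vigorous
#: physical activity (hrs/week), and afternoon vs morning blood draw.
PRIMARY_COVARIATES = ("college_grad", "vigorous_activity_hrs_wk", "afternoon_draw")

#: The ten component-score exposures of the secondary analysis (alcohol
#: is not among them).
SECONDARY_COMPONENTS = (
    "vegetables", "fruit", "whole_grains", "ssb_fruit_juice",
    "nuts_legumes_soy", "epa_dha", "pufa", "red_processed_meat",
    "trans_fat", "sodium",
)

#: Sensitivity variants: subset row filters and/or added covariates.
SENSITIVITY_VARIANTS = {
    "main": {},
    "never_smokers": {"filter": ("ever_smoker", 0)},
    "excl_gdm": {"filter": ("gdm", 0)},
    "excl_ghtn": {"filter": ("ghtn", 0)},
    "adj_bmi": {"extra_covariates": ("pre_preg_bmi",)},
    "multivitamin_only": {"filter": ("multivitamin", 1)},
    "no_nausea_med": {"filter": ("nausea_med", 0)},
}

MIN_COMPLETE_ROWS = 10

RESULT_COLUMNS = ["outcome", "exposure", "estimate", "se", "ci_low", "ci_high",
                  "p", "q", "p_bonf", "n", "stratum", "variant", "family",
                  "converged", "note"]


@dataclass
class ModelSpec:
    """One model of the analysis plan."""

    outcome: str
    exposure: str
    covariates: tuple = PRIMARY_COVARIATES
    family: str = "robust_linear"  # or "logistic_detection"
    variant: str = "main"

    def __post_init__(self):
        if self.family not in ("robust_linear", "logistic_detection"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.exposure == self.outcome:
            raise ValueError("exposure must differ from outcome")


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values or Bonferroni adjustment.

    NaN entries (unfitted models) are ignored for the family size and
    propagate as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    if method.upper() == "BH":
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(q, 1.0)
    elif method.lower() == "bonferroni":
        adj = np.minimum(pv * m, 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    out[mask] = adj
    return out


def assign_modeling_stratum(detection_rate: float) -> str:
    """Map a probe's detection rate to its modeling stratum.

    <20% -> excluded; 20-60% inclusive -> binary; >60% -> continuous.
    """
    rate = float(detection_rate)
    if not (0.0 <= rate <= 1.0):
        raise ValueError("detection rate must lie in [0, 1]")
    if rate < 0.20:
        return "excluded"
    if rate <= 0.60:
        return "binary"
    return "continuous"


# --------------------------------------------------------------------------
# single-model fits
# --------------------------------------------------------------------------

def _design(df: pd.DataFrame, exposure: str, covariates) -> tuple[np.ndarray, list]:
    cols = [exposure, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"model frame missing columns: {missing}")
    return df[cols].to_numpy(dtype=float), cols


def _blank_row(**kw) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update({"stratum": "", "variant": "main", "family": "",
                "converged": False, "note": ""})
    row.update(kw)
    return row


def fit_robust_linear(df: pd.DataFrame, outcome: str, exposure: str,
                      covariates=PRIMARY_COVARIATES, variant: str = "main",
                      **huber_kwargs) -> dict:
    """Huber robust linear fit of ``outcome ~ exposure + covariates``.

    Complete-case: rows missing any model variable are dropped (the count
    is logged).  Returns one result row keyed like ``RESULT_COLUMNS``.
    """
    cols = [outcome, exposure, *covariates]
    frame = df[cols].dropna()
    dropped = len(df) - len(frame)
    if dropped:
        logger.info("robust_linear %s~%s: dropped %d incomplete rows",
                    outcome, exposure, dropped)
    if len(frame) < MIN_COMPLETE_ROWS:
        raise ValueError(
            f"only {len(frame)} complete rows for {outcome}~{exposure}; "
            f"need >= {MIN_COMPLETE_ROWS}"
        )
    if frame[outcome].nunique() <= 1:
        raise ValueError(f"degenerate fit: outcome {outcome!r} is constant")
    X, names = _design(frame, exposure, covariates)
    y = frame[outcome].to_numpy(dtype=float)
    model = HuberRegression(**huber_kwargs).fit(X, y, feature_names=names)
    ci = model.conf_int()
    j = model.names_.index(exposure)
    return _blank_row(
        outcome=outcome, exposure=exposure, estimate=model.params_[j],
        se=model.bse_[j], ci_low=ci[j, 0], ci_high=ci[j, 1],
        p=model.pvalues_[j], n=len(frame), family="robust_linear",
        variant=variant, converged=model.converged_,
        note="" if model.converged_ else "IRLS did not converge",
    )


def fit_detection_logistic(df: pd.DataFrame, outcome: str, exposure: str,
                           covariates=PRIMARY_COVARIATES,
                           variant: str = "main") -> dict:
    """Logistic fit of a binary detection outcome; log-odds per unit exposure."""
    cols = [outcome, exposure, *covariates]
    frame = df[cols].dropna()
    if len(frame) < MIN_COMPLETE_ROWS:
        raise ValueError(
            f"only {len(frame)} complete rows for {outcome}~{exposure}; "
            f"need >= {MIN_COMPLETE_ROWS}"
        )
    y = frame[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        return _blank_row(outcome=outcome, exposure=exposure, n=len(frame),
                          family="logistic_detection", variant=variant,
                          converged=False, note="single-class outcome; skipped")
    X, names = _design(frame, exposure, covariates)
    model = DetectionLogistic().fit(X, y, feature_names=names)
    ci = model.conf_int()
    j = model.names_.index(exposure)
    return _blank_row(
        outcome=outcome, exposure=exposure, estimate=model.params_[j],
        se=model.bse_[j], ci_low=ci[j, 0], ci_high=ci[j, 1],
        p=model.pvalues_[j], n=len(frame), family="logistic_detection",
        variant=variant, converged=model.converged_, note=model.note_,
    )


# --------------------------------------------------------------------------
# analysis stages
# --------------------------------------------------------------------------

def run_primary_analysis(composition: pd.DataFrame, scores: pd.DataFrame,
                         covariates: pd.DataFrame,
                         exposure: str = "ahei_total") -> pd.DataFrame:
    """Three composition outcomes vs the total AHEI score."""
    data = composition.join(scores, how="inner").join(covariates, how="inner")
    rows = [
        fit_robust_linear(data, outcome, exposure, PRIMARY_COVARIATES)
        for outcome in ("log2_total", "richness", "evenness")
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_component_analysis(composition: pd.DataFrame, scores: pd.DataFrame,
                           covariates: pd.DataFrame,
                           outcome: str = "richness") -> pd.DataFrame:
    """Ten component scores as exposures, with caloric-intake adjustment."""
    if "kcal_per_day" not in covariates.columns:
        raise ValueError("covariate table missing required column 'kcal_per_day'")
    data = composition.join(scores, how="inner").join(covariates, how="inner")
    covs = (*PRIMARY_COVARIATES, "kcal_per_day")
    rows = [
        fit_robust_linear(data, outcome, comp, covs)
        for comp in SECONDARY_COMPONENTS
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def log2_counts(normalized: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(normalized endogenous count + pseudocount), probe x sample."""
    return np.log2(normalized.endogenous + pseudocount)


def screen_composition_associated(
    normalized: CountMatrix,
    calls: pd.DataFrame,
    rates: pd.Series,
    composition: pd.DataFrame,
    measure: str = "richness",
    alpha: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Recompute the measure-associated candidate miRNA set.

    Each probe at >=20% detection is regressed on the composition measure
    (continuous stratum: robust linear on log2 counts; binary stratum:
    detection logistic); probes with Bonferroni-adjusted p < ``alpha``
    across the screen family are the candidates.
    """
    logs = log2_counts(normalized)
    x = composition[measure]
    rows = []
    for probe, rate in rates.items():
        stratum = assign_modeling_stratum(rate)
        if stratum == "excluded":
            continue
        frame = pd.DataFrame({measure: x})
        if stratum == "continuous":
            frame["y"] = logs.loc[probe]
            try:
                row = fit_robust_linear(frame, "y", measure, covariates=())
            except ValueError as exc:
                row = _blank_row(outcome=probe, note=str(exc))
        else:
            frame["y"] = calls.loc[probe]
            row = fit_detection_logistic(frame, "y", measure, covariates=())
        row["outcome"] = probe
        row["stratum"] = stratum
        rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table["p_bonf"] = adjust_pvalues(table["p"], "bonferroni")
    candidates = list(table.loc[table["p_bonf"] < alpha, "outcome"])
    return candidates, table


def run_posthoc_mirna(
    exposure: str,
    candidates,
    normalized: CountMatrix,
    calls: pd.DataFrame,
    rates: pd.Series,
    data: pd.DataFrame,
    adjust_kcal: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Per-miRNA exposure models for a candidate set, with BH/Bonferroni.

    ``data`` is the per-sample frame holding the exposure and covariates.
    Returns (result table, skip log).  An empty candidate set returns an
    empty table with the reason logged.
    """
    covs = (*PRIMARY_COVARIATES, "kcal_per_day") if adjust_kcal else PRIMARY_COVARIATES
    missing = [c for c in (exposure, *covs) if c not in data.columns]
    if missing:
        raise ValueError(f"analysis frame missing columns: {missing}")
    candidates = list(candidates)
    skip_log = []
    if not candidates:
        logger.info("post hoc %s: empty candidate set, nothing to fit", exposure)
        return pd.DataFrame(columns=RESULT_COLUMNS), ["empty candidate set"]
    logs = log2_counts(normalized)
    rows = []
    for probe in candidates:
        if probe not in rates.index:
            raise ValueError(f"candidate probe {probe!r} not in detection rates")
        stratum = assign_modeling_stratum(rates[probe])
        if stratum == "excluded":
            skip_log.append(f"{probe}: detection rate {rates[probe]:.3f} < 0.20")
            continue
        frame = data.copy()
        if stratum == "continuous":
            frame["y"] = logs.loc[probe]
            row = fit_robust_linear(frame, "y", exposure, covs)
        else:
            frame["y"] = calls.loc[probe]
            row = fit_detection_logistic(frame, "y", exposure, covs)
        row["outcome"] = probe
        row["stratum"] = stratum
        row["exposure"] = exposure
        rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(table):
        table["q"] = adjust_pvalues(table["p"], "BH")
        table["p_bonf"] = adjust_pvalues(table["p"], "bonferroni")
    return table, skip_log


def run_sensitivity(data: pd.DataFrame, outcome: str, exposure: str,
                    covariates=PRIMARY_COVARIATES,
                    family: str = "robust_linear",
                    variants=SENSITIVITY_VARIANTS) -> pd.DataFrame:
    """Re-fit one model across the sensitivity variants.

    Subsets leaving fewer than 10 complete rows are skipped with a
    warning; each row records the variant's n.
    """
    fit = fit_robust_linear if family == "robust_linear" else fit_detection_logistic
    rows = []
    for name, spec in variants.items():
        sub = data
        if "filter" in spec:
            col, keep = spec["filter"]
            if col not in data.columns:
                raise ValueError(f"sensitivity variant {name!r} needs column {col!r}")
            sub = data[data[col] == keep]
        covs = tuple(covariates) + tuple(spec.get("extra_covariates", ()))
        try:
            row = fit(sub, outcome, exposure, covs, variant=name)
        except ValueError as exc:
            warnings.warn(f"sensitivity variant {name!r} skipped: {exc}")
            continue
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# --------------------------------------------------------------------------
# overrepresentation
# --------------------------------------------------------------------------

def overrepresentation_test(hit_genes, pathway_sets: dict, background) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of hits in gene sets.

    For each pathway, p = P(overlap >= observed) drawing |hits| genes
    from the |background| universe containing |pathway ∩ background|
    successes; BH adjustment across pathways.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    hits = set(hit_genes)
    if not hits <= background:
        stray = sorted(hits - background)[:5]
        raise ValueError(f"hit genes outside the background: {stray}")
    rows = []
    for name, genes in pathway_sets.items():
        pathway = set(genes) & background
        overlap = len(hits & pathway)
        p = float(hypergeom.sf(overlap - 1, len(background), len(pathway), len(hits)))
        rows.append({"pathway": name, "n_pathway": len(pathway),
                     "n_hits": len(hits), "overlap": overlap, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_bh"] = adjust_pvalues(table["p"], "BH")
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
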