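"""End-to-end orchestration: simulate -> score -> normalize -> compose ->
associate -> enrich -> report, with a reproducibility manifest.

Every stage reads and writes plain delimited text under one run
directory, so any stage can be re-run standalone on user-supplied data
laid out the same way.  The manifest records the seed, a configuration
hash, package versions, per-stage row/probe counts and the dropped-sample
accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ahei, associations, composition, nanostring, simulate
from .countmatrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "score", "normalize", "compose", "associate", "enrich")


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    stages: tuple = ALL_STAGES[:-1]  # enrich needs user gene sets
    #: directory with covariates.csv / intakes.csv / counts.csv when the
    #: simulate stage is disabled
    input_dir: str | None = None
    cohort: simulate.CohortConfig = dataclasses.field(
        default_factory=simulate.CohortConfig)
    panel: simulate.PanelSpec = dataclasses.field(
        default_factory=simulate.PanelSpec)
    effects: simulate.EffectSpec = dataclasses.field(
        default_factory=simulate.EffectSpec)
    normalization: nanostring.NormalizationConfig = dataclasses.field(
        default_factory=nanostring.NormalizationConfig)
    #: significance gates mirroring the analysis plan
    alpha: float = 0.05
    screen_alpha: float = 0.05
    #: enrichment inputs (paths), used only when the enrich stage is on
    gmt_path: str | None = None
    hits_path: str | None = None
    background_path: str | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        if "simulate" not in self.stages and not self.input_dir:
            raise ValueError("input_dir is required when the simulate stage is off")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a nested YAML file; all keys optional."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for scalar in ("seed", "input_dir", "alpha", "screen_alpha",
                   "gmt_path", "hits_path", "background_path"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    seed = kwargs.get("seed", 0)
    cohort_kw = dict(raw.get("cohort", {}))
    cohort_kw.setdefault("seed", seed)
    kwargs["cohort"] = simulate.CohortConfig(**cohort_kw)
    kwargs["panel"] = simulate.PanelSpec(**raw.get("panel", {}))
    eff = dict(raw.get("effects", {}))
    kwargs["effects"] = simulate.EffectSpec(**eff)
    kwargs["normalization"] = nanostring.NormalizationConfig(
        **raw.get("normalization", {}))
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    import hashlib

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the manifest.

    A stage failure aborts with the failing stage named; outputs written
    before the failure are kept under a ``QUARANTINE`` marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "evpdiet",
        "version": __version__,
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": list(config.stages),
        "counts": {},
        "dropped": {},
        "notes": [],
    }
    stage = "setup"
    try:
        state: dict = {}
        for stage in config.stages:
            _STAGE_FNS[stage](config, outdir, state, manifest)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
    except Exception as exc:
        (outdir / "QUARANTINE").write_text(
            f"pipeline failed in stage {stage!r}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config, outdir, state, manifest):
    cov, intakes = simulate.generate_cohort(config.cohort)
    counts = simulate.generate_counts((cov, intakes), config.panel,
                                      config.effects, seed=config.seed)
    cov.to_csv(outdir / "covariates.csv")
    intakes.to_csv(outdir / "intakes.csv")
    counts.to_csv(outdir / "counts.csv")
    state.update(covariates=cov, intakes=intakes, raw=counts)
    manifest["counts"]["simulate"] = {
        "participants": len(cov), "probes": counts.counts.shape[0]}


def _load_inputs(config, state):
    if "raw" in state:
        return
    indir = Path(config.input_dir)
    state["covariates"] = pd.read_csv(indir / "covariates.csv",
                                      index_col="participant_id")
    state["intakes"] = pd.read_csv(indir / "intakes.csv",
                                   index_col="participant_id")
    state["raw"] = CountMatrix.from_csv(indir / "counts.csv")


def _stage_score(config, outdir, state, manifest):
    _load_inputs(config, state)
    scores = ahei.score_intake_table(
        state["intakes"][list(ahei.COMPONENT_NAMES)])
    scores.to_csv(outdir / "ahei_scores.csv")
    state["scores"] = scores
    manifest["counts"]["score"] = {"participants": len(scores)}


def _stage_normalize(config, outdir, state, manifest):
    _load_inputs(config, state)
    normalized, factors = nanostring.positive_control_normalize(state["raw"])
    lod = nanostring.compute_lod(normalized, config.normalization)
    calls = nanostring.detection_calls(normalized, lod, config.normalization)
    rates = nanostring.detection_rates(calls)
    normalized.to_csv(outdir / "normalized_counts.csv")
    factors.rename("scale_factor").to_csv(outdir / "lod_scale_factors.csv")
    lod.to_csv(outdir / "lod.csv")
    calls.to_csv(outdir / "detection.csv")
    rates.to_csv(outdir / "detection_rates.csv")
    state.update(normalized=normalized, lod=lod, calls=calls, rates=rates)
    manifest["counts"]["normalize"] = {
        "samples": normalized.n_samples,
        "lod_order": "after positive-control normalization",
    }


def _stage_compose(config, outdir, state, manifest):
    comp = composition.summarize_composition(state["normalized"], state["calls"])
    comp.to_csv(outdir / "composition.csv")
    state["composition"] = comp
    manifest["counts"]["compose"] = {
        "samples": len(comp),
        "undefined_evenness": int(comp["evenness"].isna().sum()),
    }


def _stage_associate(config, outdir, state, manifest):
    comp, scores = state["composition"], state["scores"]
    cov = state["covariates"].copy()
    cov["kcal_per_day"] = state["intakes"]["kcal_per_day"]
    n_total = len(cov)

    primary = associations.run_primary_analysis(comp, scores, cov)
    primary.to_csv(outdir / "associations_primary.tsv", sep="\t", index=False)
    manifest["dropped"]["primary"] = int(n_total - primary["n"].min())

    data = comp.join(scores).join(cov)
    sensitivity_frames = []
    components = pd.DataFrame(columns=associations.RESULT_COLUMNS)
    mirna_frames = []
    skip_log: list[str] = []

    sig_measures = primary.loc[primary["p"] < config.alpha, "outcome"]
    for measure in sig_measures:
        sensitivity_frames.append(
            associations.run_sensitivity(data, measure, "ahei_total")
            .assign(outcome=measure))
        if measure in ("richness", "evenness"):
            components = associations.run_component_analysis(
                comp, scores, cov, outcome=measure)
            components.to_csv(outdir / "associations_components.tsv",
                              sep="\t", index=False)
            candidates, screen = associations.screen_composition_associated(
                state["normalized"], state["calls"], state["rates"], comp,
                measure=measure, alpha=config.screen_alpha)
            screen.to_csv(outdir / "screen.tsv", sep="\t", index=False)
            exposures = ["ahei_total"] + list(
                components.loc[components["p"] < config.alpha, "exposure"])
            for exposure in exposures:
                table, skips = associations.run_posthoc_mirna(
                    exposure, candidates, state["normalized"], state["calls"],
                    state["rates"], data, adjust_kcal=exposure != "ahei_total")
                mirna_frames.append(table)
                skip_log += [f"{exposure}: {s}" for s in skips]
                for _, hit in table[table["q"] < config.alpha].iterrows():
                    sensitivity_frames.append(
                        associations.run_sensitivity(
                            data.assign(y=_posthoc_outcome(state, hit)),
                            "y", exposure,
                            covariates=(*associations.PRIMARY_COVARIATES,
                                        "kcal_per_day"),
                            family=hit["family"] or "robust_linear",
                        ).assign(outcome=hit["outcome"]))

    mirna = (pd.concat(mirna_frames, ignore_index=True) if mirna_frames
             else pd.DataFrame(columns=associations.RESULT_COLUMNS))
    mirna.to_csv(outdir / "associations_mirna.tsv", sep="\t", index=False)
    if sensitivity_frames:
        pd.concat(sensitivity_frames, ignore_index=True).to_csv(
            outdir / "sensitivity.tsv", sep="\t", index=False)
    (outdir / "skipped_probes.log").write_text(
        "\n".join(skip_log) + ("\n" if skip_log else ""))
    state.update(primary=primary, components=components, mirna=mirna)
    manifest["counts"]["associate"] = {
        "primary_models": len(primary),
        "component_models": len(components),
        "mirna_models": len(mirna),
        "mirna_skipped": len(skip_log),
    }


def _posthoc_outcome(state, hit_row):
    probe = hit_row["outcome"]
    if hit_row["stratum"] == "binary":
        return state["calls"].loc[probe]
    return associations.log2_counts(state["normalized"]).loc[probe]


def _stage_enrich(config, outdir, state, manifest):
    if not (config.gmt_path and config.hits_path and config.background_path):
        raise ValueError("enrich stage needs gmt_path, hits_path and background_path")
    pathways = associations.read_gmt(config.gmt_path)
    hits = set(Path(config.hits_path).read_text().split())
    background = set(Path(config.background_path).read_text().split())
    table = associations.overrepresentation_test(hits, pathways, background)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    manifest["counts"]["enrich"] = {"pathways": len(table)}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "normalize": _stage_normalize,
    "compose": _stage_compose,
    "associate": _stage_associate,
    "enrich": _stage_enrich,
}
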