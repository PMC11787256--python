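import numpy as np
import pandas as pd
import pytest

from evpdiet import (
    CohortConfig,
    EffectSpec,
    PanelSpec,
    compute_lod,
    detection_calls,
    detection_rates,
    generate_cohort,
    generate_counts,
    positive_control_normalize,
    score_intake_table,
    summarize_composition,
)
from evpdiet.ahei import COMPONENT_NAMES

SMALL_PANEL = PanelSpec(n_endogenous=120, target_mean_richness=40.0,
                        target_total_counts=6000.0)


def process(raw):
    """Raw counts -> (normalized, calls, rates, composition)."""
    normalized, _ = positive_control_normalize(raw)
    calls = detection_calls(normalized, compute_lod(normalized))
    rates = detection_rates(calls)
    comp = summarize_composition(normalized, calls)
    return normalized, calls, rates, comp


@pytest.fixture(scope="session")
def default_cohort():
    cfg = CohortConfig(seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_study():
    """A processed 60-sample study on a reduced panel with planted effects."""
    cfg = CohortConfig(n_participants=60, seed=7)
    cov, intakes = generate_cohort(cfg)
    effects = EffectSpec(exposure="red_processed_meat",
                         mirna_log2_slopes={"miR-0005": 0.15},
                         richness_slope=-1.0)
    raw = generate_counts((cov, intakes), SMALL_PANEL, effects, seed=7)
    scores = score_intake_table(intakes[list(COMPONENT_NAMES)])
    normalized, calls, rates, comp = process(raw)
    data = comp.join(scores).join(cov)
    data["kcal_per_day"] = intakes["kcal_per_day"]
    return dict(cov=cov, intakes=intakes, scores=scores, raw=raw,
                normalized=normalized, calls=calls, rates=rates,
                comp=comp, data=data, effects=effects)
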