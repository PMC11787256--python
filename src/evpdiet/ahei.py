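"""AHEI-2010 diet-quality scoring.

The Alternative Healthy Eating Index 2010 awards 0-10 points per dietary
component and sums 11 components to a 0-110 adherence score.  Components
fall into three scoring modes:

* ``linear`` -- linear interpolation between an intake anchored at score 0
  and an intake anchored at score 10, clamped to [0, 10].  Reverse-coded
  components (red/processed meat, sugar-sweetened beverages, trans fat)
  simply have their score-0 anchor above their score-10 anchor.
* ``alcohol_j_shape`` -- J-shaped: abstainers get 2.5, a moderate window
  scores 10, heavy consumption (>= 2.5 drinks/day) scores 0, with linear
  ramps between the knots.
* ``cohort_decile`` -- sodium has no absolute anchors; participants are
  ranked within the cohort and deciles map linearly onto 0-10 (reverse:
  lowest-sodium decile scores 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComponentDefinition",
    "DEFAULT_COMPONENTS",
    "COMPONENT_NAMES",
    "AHEIScorer",
    "score_linear_component",
    "score_alcohol",
    "score_cohort_decile",
    "total_ahei",
    "load_anchors",
]


@dataclass(frozen=True)
class ComponentDefinition:
    """Scoring rule for one AHEI-2010 component.

    ``intake_at_0`` / ``intake_at_10`` are the intakes mapping to scores 0
    and 10; for reverse-coded components ``intake_at_0 > intake_at_10``.
    For non-linear modes the anchors are ignored.
    """

    name: str
    unit: str
    mode: str = "linear"  # linear | alcohol_j_shape | cohort_decile
    intake_at_0: float = 0.0
    intake_at_10: float = 1.0
    reverse: bool = False

    def __post_init__(self):
        if self.mode not in ("linear", "alcohol_j_shape", "cohort_decile"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if self.mode == "linear":
            if not np.isfinite([self.intake_at_0, self.intake_at_10]).all():
                raise ValueError(f"{self.name}: anchors must be finite")
            if self.intake_at_0 == self.intake_at_10:
                raise ValueError(f"{self.name}: anchors must differ for linear mode")


#: Default component set.  Anchors follow the original AHEI-2010 definition
#: (female anchors where the index is sex-specific; the intended cohort is
#: pregnant women).  Units are the index's native units per component.
DEFAULT_COMPONENTS: tuple[ComponentDefinition, ...] = (
    ComponentDefinition("vegetables", "servings/day", "linear", 0.0, 5.0),
    ComponentDefinition("fruit", "servings/day", "linear", 0.0, 4.0),
    ComponentDefinition("whole_grains", "g/day", "linear", 0.0, 75.0),
    ComponentDefinition("ssb_fruit_juice", "servings/day", "linear", 1.0, 0.0, reverse=True),
    ComponentDefinition("nuts_legumes_soy", "servings/day", "linear", 0.0, 1.0),
    ComponentDefinition("red_processed_meat", "servings/day", "linear", 1.5, 0.0, reverse=True),
    ComponentDefinition("trans_fat", "%energy", "linear", 4.0, 0.5, reverse=True),
    ComponentDefinition("epa_dha", "mg/day", "linear", 0.0, 250.0),
    ComponentDefinition("pufa", "%energy", "linear", 2.0, 10.0),
    ComponentDefinition("sodium", "mg/day", "cohort_decile", reverse=True),
    ComponentDefinition("alcohol", "drinks/day", "alcohol_j_shape"),
)

COMPONENT_NAMES: tuple[str, ...] = tuple(c.name for c in DEFAULT_COMPONENTS)

#: Moderate-consumption window (drinks/day) scoring 10 for women.
ALCOHOL_MODERATE_WINDOW = (0.5, 1.5)
ALCOHOL_ZERO_SCORE = 2.5
ALCOHOL_HIGH_CUTOFF = 2.5


def _validate_intake(intake) -> np.ndarray:
    arr = np.asarray(intake, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("intake must be finite")
    if (arr < 0).any():
        raise ValueError("intake must be non-negative")
    return arr


def score_linear_component(intake, definition: ComponentDefinition):
    """Score an intake by linear interpolation between the anchors.

    Works for both positive and reverse-coded components: the score is
    ``10 * clamp((x - intake_at_0) / (intake_at_10 - intake_at_0), 0, 1)``.
    """
    if definition.mode != "linear":
        raise ValueError(f"{definition.name} is not a linear-mode component")
    x = _validate_intake(intake)
    frac = (x - definition.intake_at_0) / (definition.intake_at_10 - definition.intake_at_0)
    score = 10.0 * np.clip(frac, 0.0, 1.0)
    return float(score) if np.isscalar(intake) else score


def score_alcohol(
    drinks_per_day,
    moderate_window: tuple[float, float] = ALCOHOL_MODERATE_WINDOW,
    zero_score: float = ALCOHOL_ZERO_SCORE,
    high_cutoff: float = ALCOHOL_HIGH_CUTOFF,
):
    """J-shaped alcohol score: 0 drinks -> 2.5, moderate -> 10, >= 2.5 -> 0.

    Piecewise linear between the knots, continuous on [0, inf).
    """
    x = _validate_intake(drinks_per_day)
    lo, hi = moderate_window
    score = np.empty(np.shape(x), dtype=float)
    x = np.atleast_1d(x)
    score = np.where(
        x <= lo,
        zero_score + (10.0 - zero_score) * x / lo,
        np.where(
            x <= hi,
            10.0,
            np.clip(10.0 * (high_cutoff - x) / (high_cutoff - hi), 0.0, 10.0),
        ),
    )
    return float(score[0]) if np.isscalar(drinks_per_day) else score


def score_cohort_decile(intakes, reverse: bool = True) -> np.ndarray:
    """Decile-rank scoring within a cohort (sodium's scoring rule).

    Ties get average ranks before decile binning; decile k (0..9) maps to
    ``10 * k / 9`` (reversed for reverse-coded components).  With fewer
    than 10 participants deciles are meaningless; everyone then scores 5
    with a warning, as does a constant intake vector.
    """
    x = _validate_intake(intakes)
    n = x.size
    if n < 10:
        warnings.warn("fewer than 10 participants: decile scoring degenerates to 5")
        return np.full(n, 5.0)
    if np.ptp(x) == 0:
        warnings.warn("all intakes identical: decile scores set to 5")
        return np.full(n, 5.0)
    ranks = rankdata(x, method="average")  # 1..n, ties averaged
    deciles = np.ceil(ranks / n * 10.0).astype(int) - 1  # 0..9
    deciles = np.clip(deciles, 0, 9)
    score = deciles * (10.0 / 9.0)
    if reverse:
        score = 10.0 - score
    return score


def total_ahei(components: pd.DataFrame | dict) -> pd.Series:
    """Sum the 11 component scores to the 0-110 adherence score.

    Raises if any of the 11 components is missing, naming it.
    """
    frame = pd.DataFrame(components)
    missing = [name for name in COMPONENT_NAMES if name not in frame.columns]
    if missing:
        raise ValueError(f"missing AHEI component scores: {missing}")
    sub = frame[list(COMPONENT_NAMES)]
    if ((sub < 0) | (sub > 10)).any().any():
        raise ValueError("component scores must lie in [0, 10]")
    return sub.sum(axis=1)


def load_anchors(path) -> tuple[ComponentDefinition, ...]:
    """Load component-anchor overrides from a YAML mapping.

    The file maps component name -> {intake_at_0, intake_at_10, unit, mode,
    reverse}; unspecified fields keep their defaults.
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    by_name = {c.name: c for c in DEFAULT_COMPONENTS}
    for name, overrides in spec.items():
        if name not in by_name:
            raise ValueError(f"unknown AHEI component in anchors file: {name!r}")
        by_name[name] = replace(by_name[name], **overrides)
    return tuple(by_name[n] for n in COMPONENT_NAMES)


class AHEIScorer(TransformerMixin, BaseEstimator):
    """Transform an intake table into AHEI-2010 component and total scores.

    ``fit`` learns the cohort sodium distribution (decile scoring is
    relative to the cohort); ``transform`` maps intakes to scores.  Input
    is a DataFrame with one column per component (named as in
    ``COMPONENT_NAMES``), one row per participant; output has the 11
    component score columns plus ``ahei_total``.

    Parameters
    ----------
    components : sequence of ComponentDefinition, optional
        Scoring rules; defaults to the standard AHEI-2010 set.
    moderate_window : (float, float)
        Alcohol intake window (drinks/day) awarded the full 10 points.
    """

    def __init__(self, components=DEFAULT_COMPONENTS,
                 moderate_window=ALCOHOL_MODERATE_WINDOW):
        self.components = components
        self.moderate_window = moderate_window

    def _check_input(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c.name for c in self.components if c.name not in X.columns]
        if missing:
            raise ValueError(f"intake table missing components: {missing}")
        return X

    def fit(self, X, y=None):
        X = self._check_input(X)
        # Sodium decile edges are a cohort property; freeze them at fit time
        # so new samples can be scored against the fitted cohort.
        self.decile_reference_ = {
            c.name: _validate_intake(X[c.name].to_numpy())
            for c in self.components
            if c.mode == "cohort_decile"
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "decile_reference_"):
            raise RuntimeError("AHEIScorer must be fitted before transform")
        X = self._check_input(X)
        out = pd.DataFrame(index=X.index)
        for comp in self.components:
            intake = X[comp.name].to_numpy(dtype=float)
            if comp.mode == "linear":
                out[comp.name] = score_linear_component(intake, comp)
            elif comp.mode == "alcohol_j_shape":
                out[comp.name] = score_alcohol(intake, self.moderate_window)
            else:  # cohort_decile: rank against the fitted cohort
                ref = self.decile_reference_[comp.name]
                if np.array_equal(ref, intake):
                    out[comp.name] = score_cohort_decile(intake, reverse=comp.reverse)
                else:
                    pooled = np.concatenate([ref, intake])
                    pooled_scores = score_cohort_decile(pooled, reverse=comp.reverse)
                    out[comp.name] = pooled_scores[ref.size:]
        out["ahei_total"] = total_ahei(out)
        return out


def score_intake_table(intakes: pd.DataFrame, components=DEFAULT_COMPONENTS) -> pd.DataFrame:
    """One-shot scoring of a full cohort intake table."""
    return AHEIScorer(components=components).fit(intakes).transform(intakes)
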