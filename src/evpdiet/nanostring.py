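"""NanoString nCounter count processing.

Three stages, mirroring standard nCounter practice for miRNA panels:

1. Positive-control normalization: each sample's counts are rescaled so
   the geometric mean of its six synthetic positive-control probes equals
   the across-sample average of those geometric means (the "geo.mean"
   code-count correction).
2. Sample-specific limit of detection (LOD): mean + ``lod_multiplier``
   (default 1.5) standard deviations of that sample's negative-control
   probes.
3. Detection calls: a probe is detected in a sample when its normalized
   count exceeds the sample's LOD (strict ``>`` by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin

from .countmatrix import CountMatrix

__all__ = [
    "NormalizationConfig",
    "PositiveControlNormalizer",
    "DetectionCaller",
    "positive_control_normalize",
    "compute_lod",
    "detection_calls",
    "detection_rates",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs for LOD and detection.

    lod_multiplier : multiplier on the negative-control SD (default 1.5).
    sd_flavor : "sample" (n-1 denominator, default) or "population" (n).
    comparison : "strict_greater" (default) or "greater_equal".
    """

    lod_multiplier: float = 1.5
    sd_flavor: str = "sample"
    comparison: str = "strict_greater"

    def __post_init__(self):
        if self.lod_multiplier < 0:
            raise ValueError("lod_multiplier must be >= 0")
        if self.sd_flavor not in ("sample", "population"):
            raise ValueError("sd_flavor must be 'sample' or 'population'")
        if self.comparison not in ("strict_greater", "greater_equal"):
            raise ValueError("comparison must be 'strict_greater' or 'greater_equal'")


class PositiveControlNormalizer(TransformerMixin, BaseEstimator):
    """Scale each sample so positive-control geometric means agree.

    The per-sample factor is

        f_j = mean_k[ geomean(positives_k) ] / geomean(positives_j),

    applied multiplicatively to every probe in sample j.  After the
    transform all samples share the same positive-control geometric mean,
    and re-applying the transform is the identity.

    Parameters
    ----------
    zero_policy : "error" (default) or "floor"
        Positive-control counts of zero break the geometric mean; "floor"
        adds 0.5 to zero control counts with a warning instead of raising.
    """

    def __init__(self, zero_policy: str = "error"):
        self.zero_policy = zero_policy

    def fit(self, X: CountMatrix, y=None):
        X.require_controls()
        pos = X.positives.to_numpy(dtype=float)
        if (pos <= 0).any():
            if self.zero_policy == "floor":
                import warnings

                warnings.warn("zero positive-control counts floored at +0.5")
                pos = np.where(pos <= 0, pos + 0.5, pos)
            else:
                raise ValueError(
                    "zero positive-control count encountered; "
                    "set zero_policy='floor' to proceed"
                )
        sample_geomeans = gmean(pos, axis=0)
        grand = sample_geomeans.mean()
        self.scale_factors_ = pd.Series(
            grand / sample_geomeans, index=X.counts.columns, name="scale_factor"
        )
        self.control_geomean_ = float(grand)
        return self

    def transform(self, X: CountMatrix) -> CountMatrix:
        if not hasattr(self, "scale_factors_"):
            raise RuntimeError("normalizer must be fitted first")
        if list(X.counts.columns) != list(self.scale_factors_.index):
            raise ValueError("sample ids do not match the fitted scale factors")
        out = X.copy()
        out.counts = X.counts * self.scale_factors_
        out.normalized = True
        out.meta["scale_factors"] = self.scale_factors_
        return out


def positive_control_normalize(
    raw: CountMatrix, zero_policy: str = "error"
) -> tuple[CountMatrix, pd.Series]:
    """Normalize to positive controls; returns (normalized matrix, factors)."""
    norm = PositiveControlNormalizer(zero_policy=zero_policy).fit(raw)
    return norm.transform(raw), norm.scale_factors_


def compute_lod(matrix: CountMatrix, config: NormalizationConfig | None = None) -> pd.Series:
    """Per-sample detection threshold from the negative-control probes.

    threshold_j = mean_j + lod_multiplier * sd_j over sample j's
    negative-control counts; sample SD (n-1) by default.
    """
    config = config or NormalizationConfig()
    neg = matrix.negatives.to_numpy(dtype=float)
    if neg.shape[0] < 2:
        raise ValueError("need >= 2 negative-control probes to estimate an SD")
    if (neg < 0).any():
        raise ValueError("negative-control counts must be non-negative")
    ddof = 1 if config.sd_flavor == "sample" else 0
    thresholds = neg.mean(axis=0) + config.lod_multiplier * neg.std(axis=0, ddof=ddof)
    return pd.Series(thresholds, index=matrix.counts.columns, name="lod")


def detection_calls(
    matrix: CountMatrix,
    thresholds: pd.Series,
    config: NormalizationConfig | None = None,
) -> pd.DataFrame:
    """Binary endogenous-probe x sample detection matrix."""
    config = config or NormalizationConfig()
    if set(matrix.counts.columns) != set(thresholds.index):
        raise ValueError("thresholds do not cover the matrix samples")
    thresholds = thresholds.reindex(matrix.counts.columns)
    endo = matrix.endogenous
    if config.comparison == "strict_greater":
        calls = endo.gt(thresholds, axis=1)
    else:
        calls = endo.ge(thresholds, axis=1)
    return calls.astype(int)


def detection_rates(calls: pd.DataFrame) -> pd.Series:
    """Fraction of samples in which each probe is detected."""
    return calls.mean(axis=1).rename("detection_rate")


class DetectionCaller(TransformerMixin, BaseEstimator):
    """Estimator wrapper: fit learns per-sample LODs, transform emits calls."""

    def __init__(self, config: NormalizationConfig | None = None):
        self.config = config

    def fit(self, X: CountMatrix, y=None):
        self.config_ = self.config or NormalizationConfig()
        self.thresholds_ = compute_lod(X, self.config_)
        return self

    def transform(self, X: CountMatrix) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("DetectionCaller must be fitted first")
        return detection_calls(X, self.thresholds_, self.config_)
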