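"""Per-sample miRNA repertoire composition summaries.

Three summaries describe each plasma sample's EVP miRNA repertoire:

* total counts -- sum of normalized counts over every endogenous probe
  (detected or not), log2-transformed for modeling;
* richness s -- the number of endogenous probes whose normalized count
  exceeds the sample's limit of detection, bounded by the panel size;
* evenness -- Shannon entropy of the detected probes' relative
  abundances, normalized by ln(s) so 1 means a perfectly uniform
  repertoire.  Undefined (recorded as missing) when s <= 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

__all__ = ["total_counts", "richness", "evenness", "evenness_from_abundances",
           "summarize_composition"]


def total_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Per-sample endogenous count total and its log2.

    A zero total has no log2; it is flagged as missing (NaN) with a
    warning so the sample is excluded downstream rather than silently
    imputed.
    """
    totals = matrix.endogenous.sum(axis=0)
    log2_total = pd.Series(np.nan, index=totals.index)
    positive = totals > 0
    if not positive.all():
        warnings.warn(
            f"{(~positive).sum()} sample(s) with zero total counts; "
            "log2 total flagged missing"
        )
    log2_total[positive] = np.log2(totals[positive])
    return pd.DataFrame({"total_counts": totals, "log2_total": log2_total})


def richness(calls: pd.DataFrame) -> pd.Series:
    """Number of detected endogenous probes per sample (column sums)."""
    return calls.sum(axis=0).rename("richness").astype(int)


def evenness_from_abundances(p: np.ndarray) -> float:
    """Normalized Shannon entropy  (-sum p ln p) / ln(s)  of abundances p.

    ``p`` are the relative abundances of the s detected probes; undefined
    (NaN) for s <= 1 since ln(1) = 0.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    s = p.size
    if s <= 1:
        return float("nan")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum() / np.log(s))


def evenness(matrix: CountMatrix, calls: pd.DataFrame) -> pd.Series:
    """Per-sample evenness over the detected endogenous probes."""
    endo = matrix.endogenous
    if (endo.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    calls = calls.reindex(index=endo.index, columns=endo.columns)
    values = {}
    for sample in endo.columns:
        detected = endo[sample][calls[sample] == 1]
        values[sample] = evenness_from_abundances(detected.to_numpy())
    return pd.Series(values, name="evenness")


def summarize_composition(matrix: CountMatrix, calls: pd.DataFrame) -> pd.DataFrame:
    """Combine totals, richness and evenness into one per-sample table."""
    if not matrix.normalized:
        warnings.warn("composition summaries computed on a non-normalized matrix")
    out = total_counts(matrix)
    out["richness"] = richness(calls)
    out["evenness"] = evenness(matrix, calls)
    out.index.name = "sample_id"
    return out
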