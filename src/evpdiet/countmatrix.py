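"""Probe-by-sample count matrix with NanoString-style probe classes.

The nCounter miRNA panel reports endogenous probes alongside synthetic
positive- and negative-control probes; all downstream processing (scale
normalization, limit-of-detection, detection calls) needs the class label
of every probe, so the two travel together in one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("Endogenous", "Positive", "Negative")


@dataclass
class CountMatrix:
    """Counts indexed by probe (rows) and sample (columns).

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative counts, index = probe ids, columns = sample ids.
        Integer-valued when raw; real-valued once normalized.
    probe_class : pandas.Series
        One of ``{"Endogenous", "Positive", "Negative"}`` per probe,
        aligned with ``counts.index``.
    normalized : bool
        Whether positive-control normalization has been applied.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = pd.DataFrame(self.counts)
        self.probe_class = pd.Series(self.probe_class)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if not self.counts.index.equals(self.probe_class.index):
            self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class.index[self.probe_class.isna()])[:5]
            raise ValueError(f"probes without a probe_class label: {missing}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    # -- class views -----------------------------------------------------
    def _class_frame(self, cls: str) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self._class_frame("Endogenous")

    @property
    def positives(self) -> pd.DataFrame:
        return self._class_frame("Positive")

    @property
    def negatives(self) -> pd.DataFrame:
        return self._class_frame("Negative")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def require_controls(self) -> None:
        """Raise unless at least one positive and one negative probe exist."""
        if (self.probe_class == "Positive").sum() < 1:
            raise ValueError("count matrix has no positive-control probes")
        if (self.probe_class == "Negative").sum() < 1:
            raise ValueError("count matrix has no negative-control probes")

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "probe_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "CountMatrix":
        frame = pd.read_csv(path, index_col="probe_id")
        if "probe_class" not in frame.columns:
            raise ValueError(f"{path}: missing required 'probe_class' column")
        classes = frame.pop("probe_class")
        return cls(counts=frame, probe_class=classes, normalized=normalized)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.copy(),
            probe_class=self.probe_class.copy(),
            normalized=self.normalized,
            meta=dict(self.meta),
        )
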