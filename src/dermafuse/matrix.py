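"""Samples-by-features table with aligned labels and column provenance.

``FeatureMatrix`` is the interchange object between the extraction, fusion,
selection and evaluation stages.  It is deliberately thin: a float array,
a label vector, unique column identifiers and a tag naming the producing
stage.  Persistence is plain CSV (header row of column ids plus a final
``label`` column) so every intermediate artifact of a run stays inspectable
with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]

_LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """A samples x features numeric table with per-row class labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature values, coerced to float64.
    labels : ndarray of shape (n_samples,)
        Class label per row (any hashable scalar type; kept as-is).
    column_ids : list of str
        Unique provenance strings, one per column (e.g. ``"resnet50:0017"``).
    source_tag : str
        Which stage produced the matrix: ``resnet50``, ``resnet101``,
        ``mock``, ``fused`` or ``selected``.
    """

    values: np.ndarray
    labels: np.ndarray
    column_ids: list[str] = field(default_factory=list)
    source_tag: str = "mock"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} does not match "
                f"{self.values.shape[0]} rows"
            )
        if not self.column_ids:
            self.column_ids = [
                f"{self.source_tag}:{j:04d}" for j in range((self.values.shape[1]))
            ]
        if len(self.column_ids) != self.values.shape[1]:
            raise ValueError("one column id required per feature column")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("column_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, idx, source_tag: str | None = None) -> "FeatureMatrix":
        """Return a new matrix keeping the columns in ``idx`` (in order)."""
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            column_ids=[self.column_ids[j] for j in idx],
            source_tag=source_tag or self.source_tag,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.column_ids)
        df[_LABEL_COLUMN] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source_tag: str = "mock") -> "FeatureMatrix":
        df = pd.read_csv(path)
        if _LABEL_COLUMN not in df.columns:
            raise ValueError(f"{path}: missing required '{_LABEL_COLUMN}' column")
        labels = df.pop(_LABEL_COLUMN).to_numpy()
        return cls(
            values=df.to_numpy(dtype=np.float64),
            labels=labels,
            column_ids=[str(c) for c in df.columns],
            source_tag=source_tag,
        )
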