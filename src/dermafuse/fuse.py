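"""Modified serial feature fusion with an SEM threshold.

Two feature matrices extracted from the same samples are concatenated
column-wise (an n-dimensional and an m-dimensional vector fuse to n+m
dimensions; two 2048-wide deep-feature blocks fuse to 4096).  The fused
block is then reduced by a standard-error-of-the-mean rule: summarize
each column j by its mean over samples, c_j; compute the sample standard
deviation s of the summary vector (n-1 denominator) and

    SEM = s / sqrt(d),   d = number of fused columns;

keep column j iff c_j >= SEM (ties kept).  On ReLU-derived deep features
all c_j are nonnegative, so the rule discards columns whose average
activation falls below the standard error of the column-mean profile;
on signed inputs, negative-mean columns are always discarded whenever
SEM > 0.  The whole module is deterministic.

The per-column summary is pluggable (``summary_fn``) because the
thresholded quantity admits more than one reading; the per-column mean
is the default since the output is a reduced-width feature vector.
Note the grand mean of all entries equals the mean of the per-column
means whenever columns share a sample count, so the two natural
readings of the centering term coincide here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import FeatureMatrix

__all__ = ["FusionResult", "serial_concat", "sem_threshold", "fuse", "SEMThreshold"]


@dataclass
class FusionResult:
    """Outcome of SEM thresholding on a (possibly fused) feature matrix."""

    fused: FeatureMatrix
    kept_idx: np.ndarray
    discarded_idx: np.ndarray
    sem: float
    s: float
    column_summary: np.ndarray


def serial_concat(f1: FeatureMatrix, f2: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two matrices over identical samples."""
    if f2.n_features == 0 or f1.n_features == 0:
        raise ValueError("cannot fuse a zero-width feature matrix")
    if f1.n_samples != f2.n_samples:
        raise ValueError(
            f"row count mismatch: {f1.n_samples} vs {f2.n_samples}"
        )
    mismatch = np.nonzero(f1.labels != f2.labels)[0]
    if mismatch.size:
        raise ValueError(f"label mismatch at row {int(mismatch[0])}")
    ids = [f"a|{c}" for c in f1.column_ids] + [f"b|{c}" for c in f2.column_ids]
    return FeatureMatrix(
        values=np.hstack([f1.values, f2.values]),
        labels=f1.labels.copy(),
        column_ids=ids,
        source_tag="fused",
    )


class SEMThreshold(BaseEstimator, TransformerMixin):
    """Keep columns whose summary statistic clears the SEM of all summaries.

    scikit-learn transformer: ``fit`` computes the per-column summaries,
    their sample standard deviation ``s_`` and ``sem_``, and the kept /
    discarded index partition; ``transform`` selects the kept columns.

    Parameters
    ----------
    summary_fn : callable, optional
        Maps the (n_samples, n_features) array to a length-n_features
        summary vector; defaults to the column mean.
    """

    def __init__(self, summary_fn: Callable[[np.ndarray], np.ndarray] | None = None):
        self.summary_fn = summary_fn

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        summarize = self.summary_fn or (lambda a: a.mean(axis=0))
        c = np.asarray(summarize(X), dtype=float)
        if c.shape != (X.shape[1],):
            raise ValueError("summary_fn must return one value per column")
        self.column_summary_ = c
        self.s_ = float(np.std(c, ddof=1)) if c.size > 1 else 0.0
        self.sem_ = self.s_ / np.sqrt(c.size)
        keep = c >= self.sem_
        self.kept_idx_ = np.nonzero(keep)[0]
        self.discarded_idx_ = np.nonzero(~keep)[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_idx_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("transform width differs from fit width")
        return X[:, self.kept_idx_]


def sem_threshold(
    fused: FeatureMatrix,
    summary_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FusionResult:
    """Apply the SEM keep/discard rule to a feature matrix."""
    if fused.n_features == 0 or fused.n_samples == 0:
        raise ValueError("SEM threshold needs a non-empty matrix")
    thr = SEMThreshold(summary_fn=summary_fn).fit(fused.values)
    return FusionResult(
        fused=fused.subset_columns(thr.kept_idx_, source_tag="fused"),
        kept_idx=thr.kept_idx_,
        discarded_idx=thr.discarded_idx_,
        sem=thr.sem_,
        s=thr.s_,
        column_summary=thr.column_summary_,
    )


def fuse(f1: FeatureMatrix, f2: FeatureMatrix, **kwargs) -> FusionResult:
    """Serial concatenation followed by SEM thresholding."""
    return sem_threshold(serial_concat(f1, f2), **kwargs)
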