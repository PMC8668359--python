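"""Synthetic labeled images and feature matrices with known structure.

Every downstream stage — augmentation, extraction, fusion, selection and
evaluation — is testable without downloading a dermoscopy dataset.  Two
generators are provided:

* :func:`make_synthetic_features` draws a Gaussian class-blob feature
  table with a known partition into informative columns (class-dependent
  means, pairwise separated by ``separation`` noise standard deviations)
  and pure-noise columns (i.i.d. standard normal, independent of labels).
  Deep features taken after a ReLU are nonnegative; ``nonnegative=True``
  pushes the draws through a softplus to emulate that regime, which
  matters to mean-based thresholding downstream.

* :func:`make_synthetic_images` renders small RGB rasters where each
  class is a distinct parametric family (class-specific blob radius and
  hue on a noisy background), so augmentation and feature extraction have
  non-degenerate, classifiable input.  No attempt is made at
  photorealism: the pipeline never inspects image semantics.

Both are bit-deterministic under a fixed seed and exactly class-balanced
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .images import ImageRecord, ImageSet
from .matrix import FeatureMatrix

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticImageSpec",
    "make_synthetic_features",
    "make_synthetic_images",
]


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Recipe for a Gaussian class-blob feature matrix."""

    n_per_class: int
    n_classes: int
    d_informative: int
    d_noise: int
    separation: float = 3.0
    nonnegative: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.d_informative + self.d_noise < 1:
            raise ValueError("need at least one feature column")
        if self.d_informative < 0 or self.d_noise < 0:
            raise ValueError("column counts must be nonnegative")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a class-per-subfolder synthetic RGB image set."""

    n_per_class: int
    n_classes: int
    height: int = 64
    width: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.height < 8 or self.width < 8:
            raise ValueError("height and width must be >= 8")


def _class_centers(spec: SyntheticFeatureSpec, rng: np.random.Generator) -> np.ndarray:
    """Class means in the informative subspace, pairwise ~`separation` apart.

    When the subspace has at least one axis per class the centers sit on a
    scaled simplex (coordinate vectors at separation/sqrt(2)), giving an
    exact pairwise distance; otherwise random directions are rescaled so
    the mean pairwise distance equals the requested separation.
    """
    k, d = spec.n_classes, spec.d_informative
    if d == 0:
        return np.zeros((k, 0))
    if d >= k:
        centers = np.zeros((k, d))
        for c in range(k):
            centers[c, c] = spec.separation / np.sqrt(2.0)
        return centers
    centers = rng.standard_normal((k, d))
    dists = [
        np.linalg.norm(centers[i] - centers[j])
        for i in range(k)
        for j in range(i + 1, k)
    ]
    mean_dist = float(np.mean(dists))
    if mean_dist > 0:
        centers *= spec.separation / mean_dist
    return centers


def make_synthetic_features(
    spec: SyntheticFeatureSpec,
) -> tuple[FeatureMatrix, np.ndarray, set[int]]:
    """Draw a class-blob feature table.

    Returns the matrix, the integer label vector and the set of
    informative column indices (the first ``d_informative`` columns).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    d = spec.d_informative + spec.d_noise
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    centers = _class_centers(spec, rng)
    values = rng.standard_normal((n, d))
    if spec.d_informative:
        values[:, : spec.d_informative] += centers[labels]
    if spec.nonnegative:
        values = np.logaddexp(0.0, values)  # softplus, emulates ReLU features
    fm = FeatureMatrix(
        values=values,
        labels=labels,
        column_ids=[
            f"synth:{'inf' if j < spec.d_informative else 'noise'}:{j:04d}"
            for j in range(d)
        ],
        source_tag="mock",
    )
    return fm, labels, set(range(spec.d_informative))


def make_synthetic_images(spec: SyntheticImageSpec) -> ImageSet:
    """Render a balanced RGB image set with one parametric family per class.

    Class c draws a filled disc of class-specific radius and hue at a
    jittered center over speckle noise, so classes are linearly separable
    in pixel space yet individual images differ.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    records = []
    for c in range(spec.n_classes):
        # deterministic per-class generator parameters
        radius = (0.12 + 0.30 * c / max(spec.n_classes - 1, 1)) * min(h, w)
        hue = np.array(
            [
                120 + 120 * np.sin(2.1 * c),
                120 + 120 * np.sin(2.1 * c + 2.09),
                120 + 120 * np.sin(2.1 * c + 4.19),
            ]
        ).clip(20, 235)
        for i in range(spec.n_per_class):
            cy = h / 2 + rng.uniform(-0.1, 0.1) * h
            cx = w / 2 + rng.uniform(-0.1, 0.1) * w
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            img = rng.integers(20, 60, size=(h, w, 3)).astype(np.float64)
            img[mask] = hue + rng.normal(0, 8, size=(int(mask.sum()), 3))
            records.append(
                ImageRecord(
                    pixels=img.clip(0, 255).astype(np.uint8),
                    class_label=f"class{c}",
                    image_id=f"class{c}/{i:05d}",
                )
            )
    return ImageSet(records)


def write_feature_csv(path: str | Path, fm: FeatureMatrix) -> None:
    """Persist a feature matrix as CSV (column ids header + label column)."""
    fm.to_csv(path)
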