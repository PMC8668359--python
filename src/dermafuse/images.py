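"""Labeled raster images grouped by class.

An :class:`ImageSet` mirrors the on-disk layout used throughout the
pipeline: one subdirectory per class, one PNG/JPEG file per image.  Each
:class:`ImageRecord` carries a provenance string distinguishing originals
from augmented copies (and, for the latter, the operation chain that
produced them, e.g. ``"rot90+lr"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ImageRecord", "ImageSet"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class ImageRecord:
    """A single labeled raster image.

    pixels is an H x W x C (or H x W) uint8 array; provenance is
    ``"original"`` or the augmentation chain string.
    """

    pixels: np.ndarray
    class_label: str
    image_id: str
    provenance: str = "original"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be H x W or H x W x C")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")


@dataclass
class ImageSet:
    """An ordered collection of labeled images."""

    records: list[ImageRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.class_label] = counts.get(rec.class_label, 0) + 1
        return counts

    @property
    def classes(self) -> list[str]:
        return sorted({rec.class_label for rec in self.records})

    def by_id(self) -> dict[str, ImageRecord]:
        return {rec.image_id: rec for rec in self.records}

    def save_tree(self, root: str | Path) -> None:
        """Write the set as a class-per-subfolder PNG tree."""
        root = Path(root)
        for rec in self.records:
            class_dir = root / rec.class_label
            class_dir.mkdir(parents=True, exist_ok=True)
            name = rec.image_id.split("/")[-1]
            Image.fromarray(rec.pixels).save(class_dir / f"{name}.png")

    @classmethod
    def load_tree(cls, root: str | Path) -> "ImageSet":
        """Read a class-per-subfolder image tree; non-images are skipped."""
        root = Path(root)
        if not root.is_dir():
            raise FileNotFoundError(f"image tree not found: {root}")
        records = []
        for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(class_dir.iterdir()):
                if f.suffix.lower() not in _IMAGE_SUFFIXES:
                    continue
                pixels = np.asarray(Image.open(f).convert("RGB"))
                records.append(
                    ImageRecord(
                        pixels=pixels,
                        class_label=class_dir.name,
                        image_id=f"{class_dir.name}/{f.stem}",
                    )
                )
        if not records:
            raise ValueError(f"no readable images under {root}")
        return cls(records)
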