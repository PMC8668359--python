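"""Geometric augmentation and class-balancing.

Three rigid operators — up/down flip, left/right flip and a 90-degree
rotation — are composed into chains to grow under-represented classes
until every class holds exactly ``target_per_class`` images; classes above
the target are randomly downsampled (seeded).  With seven dermoscopy
classes and a target of 6000 this yields the canonical 42,000-image
balanced set from the original imbalanced ~10,000.

All three operators are pure index remaps, so they preserve the multiset
of pixel values per channel, and they generate a small group:
``flip_ud`` and ``flip_lr`` are involutions, ``rotate90`` has order four.
The planner is deterministic under a seed: single operators are applied to
every original first (rot90, lr, ud), then length-2 chains, and so on,
with the final partial round drawn by a seeded shuffle of the sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .images import ImageRecord, ImageSet

__all__ = [
    "flip_ud",
    "flip_lr",
    "rotate90",
    "apply_chain",
    "AugmentationPlan",
    "plan_balancing",
    "apply_plan",
]

#: rotation direction used by :func:`rotate90`; "ccw" (default) or "cw".
ROTATION_DIRECTIONS = ("ccw", "cw")


def _check_raster(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim not in (2, 3):
        raise ValueError("expected an H x W or H x W x C raster")
    return pixels


def flip_ud(img: ImageRecord) -> ImageRecord:
    """Vertical flip: output row i is input row (m+1-i), channels untouched."""
    pixels = _check_raster(img.pixels)
    return ImageRecord(
        pixels=pixels[::-1].copy(),
        class_label=img.class_label,
        image_id=img.image_id,
        provenance=_chain_tag(img.provenance, "ud"),
    )


def flip_lr(img: ImageRecord) -> ImageRecord:
    """Horizontal flip: output column j is input column (n+1-j)."""
    pixels = _check_raster(img.pixels)
    return ImageRecord(
        pixels=pixels[:, ::-1].copy(),
        class_label=img.class_label,
        image_id=img.image_id,
        provenance=_chain_tag(img.provenance, "lr"),
    )


def rotate90(img: ImageRecord, direction: str = "ccw") -> ImageRecord:
    """Rigid 90-degree rotation (transpose plus one flip); H x W -> W x H.

    The rotation matrix fixes only the angle, not its sign; counter-clockwise
    is the default and clockwise is available via ``direction="cw"``.
    """
    if direction not in ROTATION_DIRECTIONS:
        raise ValueError(f"direction must be one of {ROTATION_DIRECTIONS}")
    pixels = _check_raster(img.pixels)
    k = 1 if direction == "ccw" else -1
    return ImageRecord(
        pixels=np.rot90(pixels, k=k).copy(),
        class_label=img.class_label,
        image_id=img.image_id,
        provenance=_chain_tag(img.provenance, "rot90"),
    )


_OPS = {"ud": flip_ud, "lr": flip_lr, "rot90": rotate90}


def _chain_tag(prev: str, op: str) -> str:
    return op if prev == "original" else f"{prev}+{op}"


def apply_chain(
    img: ImageRecord, chain: tuple[str, ...], direction: str = "ccw"
) -> ImageRecord:
    """Apply a sequence of operator names left to right."""
    out = img
    for op in chain:
        if op not in _OPS:
            raise ValueError(f"unknown operation {op!r}")
        out = rotate90(out, direction) if op == "rot90" else _OPS[op](out)
    return out


def _chain_sequence(length_limit: int = 6):
    """Yield operation chains: all length-1, then length-2, ... in fixed order."""
    base = ("rot90", "lr", "ud")
    for length in range(1, length_limit + 1):
        yield from product(base, repeat=length)


@dataclass
class AugmentationPlan:
    """Per-class schedule turning an imbalanced set into a balanced one.

    ``augment`` maps class -> list of (source image id, operation chain);
    ``downsample`` maps class -> set of image ids to drop.  Executing the
    plan leaves every class at exactly ``target_per_class`` images.
    """

    target_per_class: int
    augment: dict[str, list[tuple[str, tuple[str, ...]]]] = field(default_factory=dict)
    downsample: dict[str, set[str]] = field(default_factory=dict)

    def planned_count(self, cls: str, original_count: int) -> int:
        """Output size of ``cls`` after execution, given its original count."""
        kept = original_count - len(self.downsample.get(cls, set()))
        return kept + len(self.augment.get(cls, []))

    def total_planned(self, class_counts: dict[str, int]) -> int:
        return sum(self.planned_count(c, n) for c, n in class_counts.items())

    def to_dict(self) -> dict:
        return {
            "target_per_class": self.target_per_class,
            "augment": {
                c: [[src, list(chain)] for src, chain in entries]
                for c, entries in self.augment.items()
            },
            "downsample": {c: sorted(ids) for c, ids in self.downsample.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationPlan":
        return cls(
            target_per_class=int(d["target_per_class"]),
            augment={
                c: [(src, tuple(chain)) for src, chain in entries]
                for c, entries in d["augment"].items()
            },
            downsample={c: set(ids) for c, ids in d["downsample"].items()},
        )


def plan_balancing(
    class_counts: dict[str, int],
    target_per_class: int,
    seed: int = 0,
    image_ids: dict[str, list[str]] | None = None,
) -> AugmentationPlan:
    """Build a deterministic plan bringing every class to the target count.

    Classes below the target receive operation chains drawn by cycling the
    three base operators over all originals, then their length-2
    compositions, and so on; the truncated final round picks sources by a
    seeded shuffle.  Classes above the target get a seeded random
    downsample set.

    ``image_ids`` optionally names each class's images; synthetic
    ``<class>/<index>`` ids are generated otherwise so a plan can be built
    from bare counts.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    for cls_name, n in class_counts.items():
        if n < 1:
            raise ValueError(f"class {cls_name!r} has no images")

    rng = np.random.default_rng(seed)
    plan = AugmentationPlan(target_per_class=target_per_class)
    for cls_name in sorted(class_counts):
        n = class_counts[cls_name]
        ids = (
            list(image_ids[cls_name])
            if image_ids is not None
            else [f"{cls_name}/{i:05d}" for i in range(n)]
        )
        if len(ids) != n:
            raise ValueError(f"class {cls_name!r}: ids do not match count")
        if n > target_per_class:
            drop = rng.choice(n, size=n - target_per_class, replace=False)
            plan.downsample[cls_name] = {ids[i] for i in drop}
        elif n < target_per_class:
            deficit = target_per_class - n
            entries: list[tuple[str, tuple[str, ...]]] = []
            chains = _chain_sequence()
            while deficit > 0:
                chain = next(chains)
                if deficit >= n:
                    entries.extend((src, chain) for src in ids)
                    deficit -= n
                else:
                    pick = rng.permutation(n)[:deficit]
                    entries.extend((ids[i], chain) for i in sorted(pick))
                    deficit = 0
            plan.augment[cls_name] = entries
    return plan


def apply_plan(
    images: ImageSet, plan: AugmentationPlan, direction: str = "ccw"
) -> ImageSet:
    """Execute a balancing plan: drop downsampled originals, append augments."""
    index = images.by_id()
    for cls_name, entries in plan.augment.items():
        for src, _ in entries:
            if src not in index:
                raise KeyError(f"plan references unknown image id {src!r}")
    records: list[ImageRecord] = []
    for rec in images:
        if rec.image_id in plan.downsample.get(rec.class_label, set()):
            continue
        records.append(rec)
    for cls_name in sorted(plan.augment):
        for src, chain in plan.augment[cls_name]:
            out = apply_chain(index[src], chain, direction)
            out.image_id = f"{src}#{'+'.join(chain)}"
            records.append(out)
    return ImageSet(records)
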