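"""End-to-end orchestration: augment -> extract -> fuse -> select -> evaluate.

A :class:`RunConfig` describes which stages run and with what settings;
:func:`run_pipeline` executes them in order, persists every intermediate
artifact under the output directory, and writes a manifest recording
per-stage seeds, content hashes and the feature-width trajectory
(per-backbone width -> concatenated -> post-SEM -> post-selection).
Every stage can also run standalone from persisted intermediates via the
CLI, because extraction and desk-scale fusion/selection often run on
different machines.

The global seed is split deterministically into per-stage sub-seeds, so
a rerun with an identical config reproduces identical manifests
(hash-for-hash) when the mock backbones are used.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import apply_plan, plan_balancing
from .backbone import BackboneConfig, build_feature_extractor, extract_features
from .evaluate import run_zoo
from .fixtures import SyntheticImageSpec, make_synthetic_images
from .fuse import fuse
from .images import ImageSet
from .matrix import FeatureMatrix
from .select import SelectionConfig, select_features

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_STAGES = ("augment", "extract", "fuse", "select", "evaluate")


@dataclass
class RunConfig:
    """A single reproducible pipeline run."""

    out_dir: str
    input_dir: str | None = None  # None -> synthetic fixture images
    synthetic: SyntheticImageSpec | None = None
    stages: tuple[str, ...] = _STAGES
    target_per_class: int | None = None  # None -> max class count
    backbones: tuple[str, ...] = ("mock", "mock")
    feature_width: int = 64
    input_size: int = 32
    selection: SelectionConfig | None = None
    protocol: str = "cv"
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of configuration errors (empty when the config is ok)."""
    errors = []
    if cfg.seed < 0:
        errors.append("seed must be nonnegative")
    for s in cfg.stages:
        if s not in _STAGES:
            errors.append(f"unknown stage {s!r}")
    if cfg.input_dir is not None and not Path(cfg.input_dir).is_dir():
        errors.append(f"input directory does not exist: {cfg.input_dir}")
    if cfg.input_dir is None and cfg.synthetic is None:
        errors.append("either input_dir or a synthetic image spec is required")
    if cfg.protocol not in ("cv", "holdout"):
        errors.append("protocol must be 'cv' or 'holdout'")
    if len(cfg.backbones) not in (1, 2):
        errors.append("one or two backbones required")
    return errors


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _hash_images(images: ImageSet) -> str:
    h = hashlib.sha256()
    for rec in images:
        h.update(rec.pixels.tobytes())
        h.update(rec.class_label.encode())
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and persist) the manifest."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, _sub_seeds(cfg.seed, len(_STAGES))))
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "stages_run": [],
        "stages_skipped": [s for s in _STAGES if s not in cfg.stages],
        "dimensions": {},
        "hashes": {},
        "timings": {},
    }

    def _checkpoint():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        if cfg.input_dir is not None:
            images = ImageSet.load_tree(cfg.input_dir)
        else:
            images = make_synthetic_images(cfg.synthetic)
        manifest["dimensions"]["raw_images"] = len(images)
        manifest["hashes"]["raw_images"] = _hash_images(images)

        if "augment" in cfg.stages:
            t0 = time.perf_counter()
            counts = images.class_counts
            target = cfg.target_per_class or max(counts.values())
            ids = {}
            for rec in images:
                ids.setdefault(rec.class_label, []).append(rec.image_id)
            plan = plan_balancing(counts, target, seed=seeds["augment"], image_ids=ids)
            images = apply_plan(images, plan)
            (out / "augmentation_plan.json").write_text(
                json.dumps(plan.to_dict(), indent=2)
            )
            manifest["dimensions"]["augmented_images"] = len(images)
            manifest["hashes"]["augmented_images"] = _hash_images(images)
            manifest["timings"]["augment"] = time.perf_counter() - t0
            manifest["stages_run"].append("augment")
            _checkpoint()

        matrices: list[FeatureMatrix] = []
        if "extract" in cfg.stages:
            t0 = time.perf_counter()
            for i, arch in enumerate(cfg.backbones):
                bc = BackboneConfig(
                    architecture=arch,
                    n_classes=max(len(images.classes), 2),
                    input_size=cfg.input_size,
                    feature_width=cfg.feature_width,
                    seed=seeds["extract"] + i,
                )
                fm = extract_features(build_feature_extractor(bc), images)
                fm.to_csv(out / f"features_{i}_{arch}.csv")
                matrices.append(fm)
                manifest["dimensions"][f"backbone_{i}_width"] = fm.n_features
                manifest["hashes"][f"backbone_{i}"] = _hash_array(fm.values)
            manifest["timings"]["extract"] = time.perf_counter() - t0
            manifest["stages_run"].append("extract")
            _checkpoint()

        current: FeatureMatrix | None = matrices[0] if matrices else None
        if "fuse" in cfg.stages:
            if len(matrices) < 2:
                raise RuntimeError("fuse stage needs two extracted matrices")
            t0 = time.perf_counter()
            res = fuse(matrices[0], matrices[1])
            current = res.fused
            current.to_csv(out / "fused.csv")
            manifest["dimensions"]["concatenated_width"] = (
                matrices[0].n_features + matrices[1].n_features
            )
            manifest["dimensions"]["post_sem_width"] = current.n_features
            manifest["fusion"] = {
                "s": res.s,
                "sem": res.sem,
                "kept": int(res.kept_idx.size),
                "discarded": int(res.discarded_idx.size),
            }
            manifest["hashes"]["fused"] = _hash_array(current.values)
            manifest["timings"]["fuse"] = time.perf_counter() - t0
            manifest["stages_run"].append("fuse")
            _checkpoint()

        if "select" in cfg.stages:
            if current is None:
                raise RuntimeError("select stage needs features")
            t0 = time.perf_counter()
            sel_cfg = cfg.selection or SelectionConfig(seed=seeds["select"])
            res = select_features(current, cfg=sel_cfg)
            current = current.subset_columns(res.selected_idx, source_tag="selected")
            current.to_csv(out / "selected.csv")
            manifest["dimensions"]["post_selection_width"] = current.n_features
            manifest["selection"] = {
                "skew": res.skew,
                "iterations_run": res.iterations_run,
                "fitness_trace": res.fitness_trace,
                "converged": res.converged,
            }
            manifest["hashes"]["selected"] = _hash_array(current.values)
            manifest["timings"]["select"] = time.perf_counter() - t0
            manifest["stages_run"].append("select")
            _checkpoint()

        if "evaluate" in cfg.stages:
            if current is None:
                raise RuntimeError("evaluate stage needs features")
            t0 = time.perf_counter()
            report = run_zoo(
                current,
                protocol=cfg.protocol,
                k=cfg.cv_folds,
                seed=seeds["evaluate"],
            )
            (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
            manifest["evaluation"] = {
                "protocol": report.protocol,
                "best": report.best.name,
                "best_accuracy_pct": report.best.accuracy_pct,
            }
            manifest["timings"]["evaluate"] = time.perf_counter() - t0
            manifest["stages_run"].append("evaluate")
            _checkpoint()
    except Exception as exc:
        manifest["failed_stage"] = next(
            (s for s in cfg.stages if s not in manifest["stages_run"]), "input"
        )
        manifest["error"] = str(exc)
        _checkpoint()
        raise

    _checkpoint()
    return manifest
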