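"""Deep-feature extraction contract.

Features for classification are tapped at the global average pooling
(GAP) layer of a residual network whose final fully connected layer has
been replaced by a fresh head sized to the lesion label space (seven
classes).  Two real architectures are provided — ResNet-50 and
ResNet-101, both with a 2048-wide GAP tap — as pure-NumPy forward passes
with seeded He-initialized weights, which is sufficient to exercise the
extraction contract (feature widths, row order, head shape) on any
machine.  A ``mock`` architecture (a fixed seeded random projection of
the flattened, resized pixels) is the test-time default so the whole
pipeline runs in seconds.

Only the classification head is ever trained here, on the GAP features,
with the configured optimizer settings; the convolutional trunk keeps
its initialization.  Training the head never changes the GAP features,
so extraction is invariant to fine-tuning state by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from sklearn.linear_model import LogisticRegression, SGDClassifier

from .images import ImageSet
from .matrix import FeatureMatrix

__all__ = [
    "BackboneConfig",
    "build_feature_extractor",
    "extract_features",
    "fine_tune",
    "MockExtractor",
    "ResNetExtractor",
]

ARCHITECTURES = ("resnet50", "resnet101", "mock")
_RESNET_STAGES = {"resnet50": (3, 4, 6, 3), "resnet101": (3, 4, 23, 3)}
_RESNET_FEATURE_WIDTH = 2048


@dataclass
class BackboneConfig:
    """Architecture and head-training hyperparameters.

    The defaults mirror the reference training recipe: SGD with learning
    rate 1e-4, 100 epochs, minibatch 64, a 224-pixel input receptive
    field and a seven-way head.  ``feature_width`` is fixed at 2048 for
    the residual architectures and free for the mock.
    """

    architecture: str = "mock"
    n_classes: int = 7
    input_size: int = 224
    feature_width: int = _RESNET_FEATURE_WIDTH
    learning_rate: float = 1e-4
    epochs: int = 100
    minibatch: int = 64
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if self.architecture in _RESNET_STAGES:
            self.feature_width = _RESNET_FEATURE_WIDTH
        if self.feature_width < 1:
            raise ValueError("feature_width must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.input_size < 8:
            raise ValueError("input_size must be >= 8")


def _resize_rgb(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to size x size x 3 float64 in [0, 1]."""
    img = Image.fromarray(np.asarray(pixels).astype(np.uint8))
    img = img.convert("RGB").resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 255.0


def _standardize(x: np.ndarray) -> np.ndarray:
    # channel-wise standardization; constants are a documented assumption
    return (x - 0.5) / 0.25


class MockExtractor:
    """Seeded random projection of flattened pixels to ``feature_width``."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        self.feature_width = cfg.feature_width
        rng = np.random.default_rng(cfg.seed)
        d_in = cfg.input_size * cfg.input_size * 3
        self._projection = rng.standard_normal((d_in, cfg.feature_width)) / np.sqrt(
            d_in
        )
        self.head: LogisticRegression | SGDClassifier | None = None

    def features_of(self, pixels: np.ndarray) -> np.ndarray:
        x = _standardize(_resize_rgb(pixels, self.cfg.input_size)).ravel()
        return x @ self._projection

    def head_width(self) -> int:
        return self.cfg.n_classes


def _he_conv(rng, kh, kw, cin, cout):
    return rng.standard_normal((kh * kw * cin, cout)) * np.sqrt(2.0 / (kh * kw * cin))


def _conv2d(x: np.ndarray, w: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """im2col convolution; x is H x W x Cin, w is (kh*kw*Cin) x Cout."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(0, 1))
    win = win[::stride, ::stride]  # Ho x Wo x Cin x kh x kw
    ho, wo = win.shape[:2]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(ho * wo, -1)
    return (cols @ w).reshape(ho, wo, -1)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1):
    x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
    return win[::stride, ::stride].max(axis=(-2, -1))


def _inorm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    # per-image, per-channel normalization keeps random-init activations
    # bounded through 50+ layers while staying batch-independent
    mu = x.mean(axis=(0, 1), keepdims=True)
    sd = x.std(axis=(0, 1), keepdims=True)
    return (x - mu) / (sd + eps)


class ResNetExtractor:
    """Forward-only bottleneck residual network with a GAP feature tap.

    Stage layout follows the standard 50/101-layer recipes: a 7x7/2 stem
    with 3x3/2 max pooling, four bottleneck stages of widths
    256/512/1024/2048 and block counts (3,4,6,3) or (3,4,23,3), global
    average pooling, and a fully connected head of ``n_classes`` outputs.
    Weights are He-initialized from the config seed; no pretraining is
    involved.
    """

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        self.feature_width = _RESNET_FEATURE_WIDTH
        rng = np.random.default_rng(cfg.seed)
        self.stem = _he_conv(rng, 7, 7, 3, 64)
        self.blocks: list[dict] = []
        cin = 64
        widths = (64, 128, 256, 512)
        for stage, n_blocks in enumerate(_RESNET_STAGES[cfg.architecture]):
            mid, cout = widths[stage], widths[stage] * 4
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                blk = {
                    "w1": _he_conv(rng, 1, 1, cin, mid),
                    "w2": _he_conv(rng, 3, 3, mid, mid),
                    "w3": _he_conv(rng, 1, 1, mid, cout),
                    "stride": stride,
                }
                if cin != cout or stride != 1:
                    blk["proj"] = _he_conv(rng, 1, 1, cin, cout)
                self.blocks.append(blk)
                cin = cout
        self.head_weights = rng.standard_normal(
            (self.feature_width, cfg.n_classes)
        ) * np.sqrt(1.0 / self.feature_width)
        self.head: LogisticRegression | SGDClassifier | None = None

    def head_width(self) -> int:
        return self.cfg.n_classes

    def features_of(self, pixels: np.ndarray) -> np.ndarray:
        x = _standardize(_resize_rgb(pixels, self.cfg.input_size))
        x = np.maximum(_inorm(_conv2d(x, self.stem, 7, 7, 2, 3)), 0.0)
        x = _maxpool(x)
        for blk in self.blocks:
            s = blk["stride"]
            out = np.maximum(_inorm(_conv2d(x, blk["w1"], 1, 1, 1, 0)), 0.0)
            out = np.maximum(_inorm(_conv2d(out, blk["w2"], 3, 3, s, 1)), 0.0)
            out = _inorm(_conv2d(out, blk["w3"], 1, 1, 1, 0))
            short = (
                _inorm(_conv2d(x, blk["proj"], 1, 1, s, 0)) if "proj" in blk else x
            )
            x = np.maximum(out + short, 0.0)
        return x.mean(axis=(0, 1))  # global average pooling -> 2048


def build_feature_extractor(cfg: BackboneConfig):
    """Instantiate the configured architecture with a fresh head."""
    if cfg.architecture == "mock":
        return MockExtractor(cfg)
    return ResNetExtractor(cfg)


def extract_features(extractor, images: ImageSet) -> FeatureMatrix:
    """Run the GAP feature tap over an image set, one row per image in order.

    Non-raster records are impossible here (ImageSet validates them), but
    an empty set is rejected.
    """
    if len(images) == 0:
        raise ValueError("cannot extract features from an empty image set")
    rows = np.stack([extractor.features_of(rec.pixels) for rec in images])
    tag = extractor.cfg.architecture
    return FeatureMatrix(
        values=rows,
        labels=np.array([rec.class_label for rec in images]),
        column_ids=[f"{tag}:{j:04d}" for j in range(rows.shape[1])],
        source_tag=tag,
    )


def fine_tune(extractor, images: ImageSet, cfg: BackboneConfig):
    """Train the classification head on GAP features of a labeled image set.

    With ``epochs=0`` the extractor is returned untouched.  The trunk is
    never updated, so feature extraction is unchanged by this call.
    """
    labels = sorted({rec.class_label for rec in images})
    if len(labels) < 2:
        raise ValueError("fine-tuning requires at least two classes")
    if len(labels) > cfg.n_classes:
        raise ValueError(
            f"{len(labels)} classes present but head width is {cfg.n_classes}"
        )
    if cfg.epochs == 0:
        return extractor
    fm = extract_features(extractor, images)
    if cfg.architecture == "mock":
        head = LogisticRegression(max_iter=200, random_state=cfg.seed)
    else:
        head = SGDClassifier(
            loss="log_loss",
            learning_rate="constant",
            eta0=cfg.learning_rate,
            max_iter=cfg.epochs,
            random_state=cfg.seed,
            tol=None,
        )
    head.fit(fm.values, fm.labels)
    extractor.head = head
    return extractor


def head_training_accuracy(extractor, images: ImageSet) -> float:
    """Training accuracy of a fitted head; raises if never fine-tuned."""
    if extractor.head is None:
        raise RuntimeError("extractor head has not been trained")
    fm = extract_features(extractor, images)
    return float(np.mean(extractor.head.predict(fm.values) == fm.labels))
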