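"""Scaled-down patch classifiers for false-positive reduction.

The second stage of the detection pipeline re-scores candidate regions as
nodule / non-nodule.  Four convolutional feature-extractor families are
provided, faithful in kind to their namesakes but reduced in size so they
run on a CPU in seconds:

* ``resnet``  — stages are bottleneck residual blocks whose output is
  literally ``transform(x) + x`` (identity shortcut);
* ``densenet`` — dense blocks in which layer l sees the concatenation of the
  stage input and all previous layer outputs, so its input channel count
  grows linearly with the growth rate;
* ``mobilenet`` — depthwise-separable blocks (per-channel 3x3 followed by a
  1x1 pointwise mix), strictly cheaper in parameters than the equivalent
  dense convolution;
* ``mixnet`` — depthwise convolution with mixed kernel sizes (1/3/5) over
  channel groups, then a pointwise mix.

Every model ends in global average pooling and a fully connected layer with
exactly two outputs (nodule vs non-nodule).  Attention blocks (SE / CA-I /
CA-II) can be inserted after each stage.  The demo trainer keeps the
randomly initialised extractor frozen and fits the two-neuron head by
full-batch gradient descent on the softmax cross-entropy — a linear probe
that is exactly reproducible under a seed and sufficient for the synthetic
patch tasks the toolkit is tested on.

3-D patches are accepted by folding the depth axis into the channel axis at
the stem (a 2.5-D reading of the volume).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .attention import AttentionBlock, make_attention

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "FusionRule",
    "PatchSample",
    "Backbone",
    "PatchClassifier",
    "TrainingDiverged",
    "build_backbone",
    "save_checkpoint",
    "load_checkpoint",
    "classify_patches",
    "fuse_multibackbone",
    "train_demo",
    "separable_conv_params",
    "standard_conv_params",
]


# ---------------------------------------------------------------------------
# minimal batched conv layers (N, C, H, W)

def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1) -> np.ndarray:
    """Same-padded 2-D convolution; w is (out_c, in_c, kh, kw)."""
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    return np.einsum("nchwij,ocij->nohw", win, w, optimize=True) + b[None, :, None, None]


def _depthwise_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-channel same-padded convolution; w is (C, kh, kw)."""
    kh, kw = w.shape[1], w.shape[2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.einsum("nchwij,cij->nchw", win, w, optimize=True) + b[None, :, None, None]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    x = x[:, :, :h2, :w2]
    return x.reshape(n, c, h2 // 2, 2, w2 // 2, 2).mean(axis=(3, 5))


def standard_conv_params(in_c: int, out_c: int, k: int) -> int:
    """Parameter count of a dense k x k convolution with bias."""
    return out_c * in_c * k * k + out_c


def separable_conv_params(in_c: int, out_c: int, k: int) -> int:
    """Parameter count of depthwise k x k + pointwise 1x1, both with bias."""
    return in_c * k * k + in_c + out_c * in_c + out_c


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class BackboneConfig:
    """Family, scale and attention of a patch classifier."""

    family: str = "resnet"
    depth_scale: float = 1.0
    width_scale: float = 1.0
    attention: str = "none"  # none | se | ca1 | ca2
    input_size: tuple[int, ...] = (24, 24)  # (H, W) or (D, H, W)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("resnet", "densenet", "mobilenet", "mixnet"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.depth_scale <= 0 or self.width_scale <= 0:
            raise ValueError("scales must be positive")
        if self.attention not in ("none", "se", "ca1", "ca2"):
            raise ValueError(f"unknown attention {self.attention!r}")
        size = tuple(int(s) for s in self.input_size)
        if len(size) not in (2, 3):
            raise ValueError("input_size must be 2-D (H, W) or 3-D (D, H, W)")
        object.__setattr__(self, "input_size", size)

    @property
    def stem_in_channels(self) -> int:
        # 3-D patches enter as depth-as-channels (2.5-D)
        return self.input_size[0] if len(self.input_size) == 3 else 1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    lr: float = 0.5
    val_fraction: float = 0.2
    l2: float = 1e-4


@dataclass(frozen=True)
class FusionRule:
    """How two backbone score vectors are fused into one decision.

    ``union_positive``: positive iff either branch's score exceeds the
    threshold (strict >).  ``mean_score``: threshold the arithmetic mean.
    """

    mode: str = "union_positive"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("union_positive", "mean_score"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PatchSample:
    """A candidate patch with its nodule / non-nodule label."""

    patch: np.ndarray
    label: int  # 1 nodule, 0 non-nodule

    def __post_init__(self) -> None:
        p = np.asarray(self.patch, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("patch values must be finite")
        object.__setattr__(self, "patch", p)


class TrainingDiverged(RuntimeError):
    """Raised when the demo trainer hits a non-finite loss; carries the trace."""

    def __init__(self, epoch: int, trace: list[float]):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch
        self.trace = trace


# ---------------------------------------------------------------------------
# stages

class _ResidualStage:
    """Bottleneck residual stage: out = transform(x) + x (identity shortcut)."""

    def __init__(self, channels: int, rng: np.random.RandomState):
        mid = max(2, channels // 2)
        self.w1 = _he(rng, (mid, channels, 1, 1))
        self.b1 = np.zeros(mid)
        self.w2 = _he(rng, (mid, mid, 3, 3))
        self.b2 = np.zeros(mid)
        self.w3 = _he(rng, (channels, mid, 1, 1))
        self.b3 = np.zeros(channels)
        self.out_channels = channels

    def transform(self, x: np.ndarray) -> np.ndarray:
        h = _relu(_conv2d(x, self.w1, self.b1))
        h = _relu(_conv2d(h, self.w2, self.b2))
        return _conv2d(h, self.w3, self.b3)

    def shortcut(self, x: np.ndarray) -> np.ndarray:
        return x

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.transform(x) + self.shortcut(x)

    def zero_transform(self) -> None:
        for w in (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3):
            w[...] = 0.0

    @property
    def num_params(self) -> int:
        return sum(a.size for a in (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3))


class _DenseStage:
    """Dense block: layer l consumes the stage input plus all earlier outputs."""

    def __init__(self, in_channels: int, growth: int, n_layers: int, rng: np.random.RandomState):
        self.layers = []
        self.layer_in_channels: list[int] = []
        c = in_channels
        for _ in range(n_layers):
            self.layer_in_channels.append(c)
            self.layers.append((_he(rng, (growth, c, 3, 3)), np.zeros(growth)))
            c += growth
        self.out_channels = c

    def __call__(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        for w, b in self.layers:
            h = _relu(_conv2d(np.concatenate(feats, axis=1), w, b))
            feats.append(h)
        return np.concatenate(feats, axis=1)

    @property
    def num_params(self) -> int:
        return sum(w.size + b.size for w, b in self.layers)


class _SeparableStage:
    """Depthwise 3x3 + pointwise 1x1 (the depthwise-separable decomposition)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.RandomState):
        self.dw = _he(rng, (in_channels, 3, 3))
        self.db = np.zeros(in_channels)
        self.pw = _he(rng, (out_channels, in_channels, 1, 1))
        self.pb = np.zeros(out_channels)
        self.out_channels = out_channels

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = _relu(_depthwise_conv2d(x, self.dw, self.db))
        return _relu(_conv2d(h, self.pw, self.pb))

    @property
    def num_params(self) -> int:
        return self.dw.size + self.db.size + self.pw.size + self.pb.size


class _MixedStage:
    """Mixed-kernel depthwise stage: channel groups use 1x1 / 3x3 / 5x5 kernels."""

    KERNELS = (1, 3, 5)

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.RandomState):
        splits = np.array_split(np.arange(in_channels), len(self.KERNELS))
        self.groups = []
        for idx, k in zip(splits, self.KERNELS):
            if len(idx) == 0:
                continue
            self.groups.append((idx, _he(rng, (len(idx), k, k)), np.zeros(len(idx))))
        self.pw = _he(rng, (out_channels, in_channels, 1, 1))
        self.pb = np.zeros(out_channels)
        self.out_channels = out_channels

    def __call__(self, x: np.ndarray) -> np.ndarray:
        parts = []
        for idx, w, b in self.groups:
            parts.append(_depthwise_conv2d(x[:, idx], w, b))
        h = _relu(np.concatenate(parts, axis=1))
        return _relu(_conv2d(h, self.pw, self.pb))

    @property
    def num_params(self) -> int:
        return (
            sum(w.size + b.size for _, w, b in self.groups) + self.pw.size + self.pb.size
        )


def _he(rng: np.random.RandomState, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.randn(*shape) * np.sqrt(2.0 / max(fan_in, 1))


# ---------------------------------------------------------------------------
# backbone

class Backbone:
    """A scaled-down feature extractor + 2-neuron head.

    Built by :func:`build_backbone`.  ``features(X)`` returns pooled feature
    vectors; ``forward(X)`` returns logits with final width exactly 2.
    """

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.RandomState(config.seed)
        base = max(4, int(round(8 * config.width_scale)))
        n_stages = max(1, int(round(2 * config.depth_scale)))
        in_c = config.stem_in_channels
        self.stem_w = _he(rng, (base, in_c, 3, 3))
        self.stem_b = np.zeros(base)
        self.stages: list = []
        self.attention_blocks: list[AttentionBlock | None] = []
        c = base
        for s in range(n_stages):
            if config.family == "resnet":
                stage = _ResidualStage(c, rng)
            elif config.family == "densenet":
                stage = _DenseStage(c, growth=max(2, base // 2), n_layers=2, rng=rng)
            elif config.family == "mobilenet":
                stage = _SeparableStage(c, min(2 * c, 4 * base), rng)
            else:
                stage = _MixedStage(c, min(2 * c, 4 * base), rng)
            self.stages.append(stage)
            c = stage.out_channels
            self.attention_blocks.append(
                make_attention(c, config.attention, rng=np.random.RandomState(config.seed + 100 + s))
            )
        self.feature_dim = c
        self.head_w = np.zeros((2, c))
        self.head_b = np.zeros(2)
        # feature normalisation fitted by the demo trainer (identity until then)
        self.feat_mean = np.zeros(c)
        self.feat_std = np.ones(c)

    # -- shape plumbing ----------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # single 2-D patch
            X = X[None]
        if X.ndim == 3 and len(self.config.input_size) == 3:
            X = X[None]  # single 3-D patch -> batch of one, depth as channels
        elif X.ndim == 3:
            X = X[:, None]  # batch of 2-D patches -> channel axis
        if X.ndim != 4:
            raise ValueError("expected a batch of 2-D or 3-D patches")
        if X.shape[1] != self.config.stem_in_channels:
            raise ValueError(
                f"patch channel/depth {X.shape[1]} does not match config "
                f"{self.config.stem_in_channels}"
            )
        # standardise each patch independently for stable magnitudes
        mu = X.mean(axis=(1, 2, 3), keepdims=True)
        sd = X.std(axis=(1, 2, 3), keepdims=True)
        return (X - mu) / (sd + 1e-8)

    def feature_maps(self, X: np.ndarray) -> np.ndarray:
        h = _relu(_conv2d(self._prepare(X), self.stem_w, self.stem_b))
        for stage, attn in zip(self.stages, self.attention_blocks):
            h = stage(h)
            if attn is not None:
                h = np.stack([attn(sample) for sample in h])
            h = _avgpool2(h) if min(h.shape[2:]) >= 2 else h
        return h

    def features(self, X: np.ndarray) -> np.ndarray:
        """Global-average-pooled descriptors, shape (n, feature_dim)."""
        return self.feature_maps(X).mean(axis=(2, 3))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Logits, shape (n, 2)."""
        feats = (self.features(X) - self.feat_mean) / self.feat_std
        return feats @ self.head_w.T + self.head_b

    @property
    def num_params(self) -> int:
        n = self.stem_w.size + self.stem_b.size + self.head_w.size + self.head_b.size
        n += sum(s.num_params for s in self.stages)
        for a in self.attention_blocks:
            if a is not None:
                n += sum(
                    v.size for v in vars(a.params).values() if isinstance(v, np.ndarray)
                )
        return n


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct a reduced-scale feature extractor of the requested family."""
    return Backbone(config)


def save_checkpoint(model: Backbone, path: str | Path) -> Path:
    """Write a self-describing JSON checkpoint.

    The frozen extractor is fully determined by the config (including its
    seed), so the checkpoint stores the config snapshot plus the trained
    quantities: the 2-neuron head and the feature-normalisation statistics.
    """
    payload = {
        "config": {**vars(model.config), "input_size": list(model.config.input_size)},
        "head_w": model.head_w.tolist(),
        "head_b": model.head_b.tolist(),
        "feat_mean": model.feat_mean.tolist(),
        "feat_std": model.feat_std.tolist(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_checkpoint(path: str | Path) -> Backbone:
    """Rebuild a model from :func:`save_checkpoint` output; inference-exact."""
    payload = json.loads(Path(path).read_text())
    cfg = dict(payload["config"])
    cfg["input_size"] = tuple(cfg["input_size"])
    model = Backbone(BackboneConfig(**cfg))
    model.head_w = np.asarray(payload["head_w"], dtype=float)
    model.head_b = np.asarray(payload["head_b"], dtype=float)
    model.feat_mean = np.asarray(payload["feat_mean"], dtype=float)
    model.feat_std = np.asarray(payload["feat_std"], dtype=float)
    return model


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classify_patches(model: Backbone, samples: np.ndarray | Sequence) -> np.ndarray:
    """Nodule probability per patch, in [0, 1]; deterministic in inference."""
    if len(samples) and isinstance(samples[0], PatchSample):
        samples = np.stack([s.patch for s in samples])
    return _softmax(model.forward(np.asarray(samples)))[:, 1]


def train_demo(
    dataset: tuple[np.ndarray, np.ndarray],
    config: BackboneConfig = BackboneConfig(),
    seed: int = 0,
    train_config: TrainConfig = TrainConfig(),
) -> tuple[Backbone, dict[str, np.ndarray]]:
    """CPU demo training: fit the 2-neuron head over frozen random features.

    Full-batch gradient descent on the softmax cross-entropy with L2
    shrinkage, deterministic under ``seed``.  Returns the trained model and a
    trace dict with per-epoch ``train_loss`` and ``val_loss`` arrays.  A
    non-finite loss raises :class:`TrainingDiverged` with the partial trace.
    """
    X, y = dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    model = Backbone(BackboneConfig(**{**vars(config), "seed": seed}))
    raw = model.features(X)
    model.feat_mean = raw.mean(axis=0)
    model.feat_std = raw.std(axis=0) + 1e-8
    feats = (raw - model.feat_mean) / model.feat_std
    rng = np.random.RandomState(seed)
    n = len(y)
    idx = rng.permutation(n)
    n_val = max(1, int(train_config.val_fraction * n)) if n > 4 else 0
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    onehot = np.eye(2)[y]

    def loss_of(subset: np.ndarray) -> float:
        if len(subset) == 0:
            return float("nan")
        p = _softmax(feats[subset] @ model.head_w.T + model.head_b)
        return float(-np.mean(np.sum(onehot[subset] * np.log(p + 1e-12), axis=1)))

    train_trace: list[float] = []
    val_trace: list[float] = []
    for epoch in range(train_config.epochs):
        train_trace.append(loss_of(tr_idx))
        val_trace.append(loss_of(val_idx))
        if not np.isfinite(train_trace[-1]):
            raise TrainingDiverged(epoch, train_trace)
        p = _softmax(feats[tr_idx] @ model.head_w.T + model.head_b)
        g = (p - onehot[tr_idx]) / len(tr_idx)  # exact softmax-CE gradient
        grad_w = g.T @ feats[tr_idx] + train_config.l2 * model.head_w
        grad_b = g.sum(axis=0)
        model.head_w -= train_config.lr * grad_w
        model.head_b -= train_config.lr * grad_b
    return model, {"train_loss": np.asarray(train_trace), "val_loss": np.asarray(val_trace)}


def fuse_multibackbone(
    scores_a: np.ndarray, scores_b: np.ndarray, rule: FusionRule = FusionRule()
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse two aligned score vectors; returns (labels, fused_scores).

    ``union_positive`` flags a sample positive when either branch's score
    strictly exceeds the threshold (fused score = max).  ``mean_score``
    averages the branches first (fused score = mean, strict >).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be aligned")
    if rule.mode == "union_positive":
        labels = (a > rule.threshold) | (b > rule.threshold)
        fused = np.maximum(a, b)
    else:
        fused = 0.5 * (a + b)
        labels = fused > rule.threshold
    return labels, fused


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper: build a backbone and linear-probe it on patches.

    ``X`` may be (n, H, W) 2-D patches or (n, D, H, W) 3-D patches matching
    ``input_size``; ``y`` is binary (1 = nodule).
    """

    def __init__(
        self,
        family: str = "resnet",
        attention: str = "none",
        width_scale: float = 1.0,
        depth_scale: float = 1.0,
        input_size: tuple[int, ...] = (24, 24),
        epochs: int = 40,
        lr: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.family = family
        self.attention = attention
        self.width_scale = width_scale
        self.depth_scale = depth_scale
        self.input_size = input_size
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def fit(self, X, y):
        cfg = BackboneConfig(
            family=self.family,
            attention=self.attention,
            width_scale=self.width_scale,
            depth_scale=self.depth_scale,
            input_size=tuple(self.input_size),
            seed=self.seed,
        )
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.model_, self.trace_ = train_demo(
            (np.asarray(X, dtype=float), y),
            cfg,
            seed=self.seed,
            train_config=TrainConfig(epochs=self.epochs, lr=self.lr),
        )
        self._feat_stats_ = None
        return self

    def predict_proba(self, X):
        return _softmax(self.model_.forward(np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.predict_proba(X)[:, 1] > 0.5

    def score_patches(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
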