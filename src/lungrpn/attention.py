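"""Channel/coordinate attention blocks.

Three gating blocks that rescale a feature map C x H x W element-wise by
sigmoid gates in (0, 1):

* **SE** (squeeze-and-excitation): global average pool per channel, a
  two-layer bottleneck (C -> C/r -> C), sigmoid, channel-wise multiply.
* **CA-I** (coordinate attention): 1-D average pooling along each spatial
  direction separately, producing a per-(channel, row) and a per-(channel,
  column) descriptor.  The two are concatenated along the spatial axis,
  passed through a shared 1x1 bottleneck with normalization and a hard-swish
  nonlinearity, split back, and expanded by per-direction 1x1 convolutions
  into a row gate and a column gate.  The output is x * gate_h * gate_w, so
  positional information along each axis survives the squeeze.
* **CA-II**: same as CA-I except each directional descriptor combines the
  average **and** the maximum along the pooled axis (the CBAM-style dual
  pooling), merged by their arithmetic mean so that on spatially constant
  input — where max equals average — CA-II degenerates exactly to CA-I.

All blocks run in inference mode: normalization uses stored statistics, so a
forward pass is a deterministic function of (input, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "AttentionConfig",
    "SEParams",
    "CAParams",
    "AttentionBlock",
    "make_attention",
    "init_se_params",
    "init_ca_params",
    "se_forward",
    "ca1_forward",
    "ca2_forward",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def hard_swish(x: np.ndarray) -> np.ndarray:
    """x * relu6(x + 3) / 6 — the nonlinearity of the coordinate-attention family."""
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def _reduced_width(channels: int, reduction_ratio: int, floor: int = 4) -> int:
    return max(min(floor, channels), channels // reduction_ratio)


@dataclass(frozen=True)
class AttentionConfig:
    """Which block to build and how narrow its bottleneck is.

    ``reduction_ratio`` r shrinks C to max(C // r, 4) hidden channels
    (clamped so the bottleneck never vanishes).
    """

    variant: Literal["se", "ca1", "ca2"] = "ca1"
    reduction_ratio: int = 16

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.variant not in ("se", "ca1", "ca2"):
            raise ValueError(f"unknown attention variant {self.variant!r}")


@dataclass
class SEParams:
    """Bottleneck weights of the SE block: C -> hidden -> C."""

    w1: np.ndarray  # (hidden, C)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (C, hidden)
    b2: np.ndarray  # (C,)


@dataclass
class CAParams:
    """Shared-transform and split weights of a coordinate-attention block.

    ``w_shared`` acts as a 1x1 convolution C -> hidden on the concatenated
    directional descriptors; BN statistics/affine are stored for inference;
    ``w_h``/``w_w`` expand hidden -> C for the row and column gates.
    """

    w_shared: np.ndarray  # (hidden, C)
    b_shared: np.ndarray  # (hidden,)
    bn_gamma: np.ndarray  # (hidden,)
    bn_beta: np.ndarray  # (hidden,)
    bn_mean: np.ndarray  # (hidden,)
    bn_var: np.ndarray  # (hidden,)
    w_h: np.ndarray  # (C, hidden)
    b_h: np.ndarray  # (C,)
    w_w: np.ndarray  # (C, hidden)
    b_w: np.ndarray  # (C,)
    bn_eps: float = 1e-5


def init_se_params(
    channels: int, reduction_ratio: int = 16, rng: np.random.RandomState | None = None
) -> SEParams:
    """He-style random init; pass ``rng=None`` for zeros (identity-free gate 0.5)."""
    hidden = _reduced_width(channels, reduction_ratio)
    if rng is None:
        return SEParams(
            np.zeros((hidden, channels)), np.zeros(hidden),
            np.zeros((channels, hidden)), np.zeros(channels),
        )
    return SEParams(
        rng.randn(hidden, channels) * np.sqrt(2.0 / channels), np.zeros(hidden),
        rng.randn(channels, hidden) * np.sqrt(2.0 / hidden), np.zeros(channels),
    )


def init_ca_params(
    channels: int, reduction_ratio: int = 16, rng: np.random.RandomState | None = None
) -> CAParams:
    hidden = _reduced_width(channels, reduction_ratio)
    if rng is None:
        w_shared = np.zeros((hidden, channels))
        w_h = np.zeros((channels, hidden))
        w_w = np.zeros((channels, hidden))
        gamma = np.zeros(hidden)
    else:
        w_shared = rng.randn(hidden, channels) * np.sqrt(2.0 / channels)
        w_h = rng.randn(channels, hidden) * np.sqrt(2.0 / hidden)
        w_w = rng.randn(channels, hidden) * np.sqrt(2.0 / hidden)
        gamma = np.ones(hidden)
    return CAParams(
        w_shared=w_shared, b_shared=np.zeros(hidden),
        bn_gamma=gamma, bn_beta=np.zeros(hidden),
        bn_mean=np.zeros(hidden), bn_var=np.ones(hidden),
        w_h=w_h, b_h=np.zeros(channels), w_w=w_w, b_w=np.zeros(channels),
    )


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("feature map must be C x H x W")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x


def se_forward(x: np.ndarray, params: SEParams) -> np.ndarray:
    """Squeeze-and-excitation gating; output shape equals input shape."""
    x = _check_input(x)
    c = x.shape[0]
    if params.w1.shape[1] != c:
        raise ValueError("parameter/channel mismatch")
    z = x.mean(axis=(1, 2))  # (C,) squeeze
    h = np.maximum(params.w1 @ z + params.b1, 0.0)  # ReLU bottleneck
    gate = sigmoid(params.w2 @ h + params.b2)  # (C,)
    return x * gate[:, None, None]


def _ca_forward(x: np.ndarray, params: CAParams, dual_pool: bool) -> np.ndarray:
    x = _check_input(x)
    c, hgt, wid = x.shape
    if params.w_shared.shape[1] != c:
        raise ValueError("parameter/channel mismatch")
    pool_h = x.mean(axis=2)  # (C, H): average along width
    pool_w = x.mean(axis=1)  # (C, W): average along height
    if dual_pool:
        pool_h = 0.5 * (pool_h + x.max(axis=2))
        pool_w = 0.5 * (pool_w + x.max(axis=1))
    cat = np.concatenate([pool_h, pool_w], axis=1)  # (C, H + W)
    mid = params.w_shared @ cat + params.b_shared[:, None]  # (hidden, H + W)
    mid = (mid - params.bn_mean[:, None]) / np.sqrt(params.bn_var[:, None] + params.bn_eps)
    mid = params.bn_gamma[:, None] * mid + params.bn_beta[:, None]
    mid = hard_swish(mid)
    mid_h, mid_w = mid[:, :hgt], mid[:, hgt:]
    gate_h = sigmoid(params.w_h @ mid_h + params.b_h[:, None])  # (C, H)
    gate_w = sigmoid(params.w_w @ mid_w + params.b_w[:, None])  # (C, W)
    return x * gate_h[:, :, None] * gate_w[:, None, :]


def ca1_forward(x: np.ndarray, params: CAParams) -> np.ndarray:
    """Coordinate attention with directional average pooling."""
    return _ca_forward(x, params, dual_pool=False)


def ca2_forward(x: np.ndarray, params: CAParams) -> np.ndarray:
    """Coordinate attention with combined average+max directional pooling."""
    return _ca_forward(x, params, dual_pool=True)


class AttentionBlock:
    """A configured attention block bound to a channel count.

    ``block(x)`` applies the gating; parameters live in ``block.params`` and
    can be serialized alongside a classifier checkpoint.
    """

    def __init__(
        self,
        channels: int,
        config: AttentionConfig = AttentionConfig(),
        rng: np.random.RandomState | None = None,
    ) -> None:
        self.channels = channels
        self.config = config
        if config.variant == "se":
            self.params = init_se_params(channels, config.reduction_ratio, rng)
        else:
            self.params = init_ca_params(channels, config.reduction_ratio, rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.config.variant == "se":
            return se_forward(x, self.params)
        if self.config.variant == "ca1":
            return ca1_forward(x, self.params)
        return ca2_forward(x, self.params)


def make_attention(
    channels: int,
    variant: str,
    reduction_ratio: int = 16,
    rng: np.random.RandomState | None = None,
) -> AttentionBlock | None:
    """Factory: ``variant='none'`` returns None (no block inserted)."""
    if variant in (None, "none"):
        return None
    return AttentionBlock(channels, AttentionConfig(variant=variant, reduction_ratio=reduction_ratio), rng)
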