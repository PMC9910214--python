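"""Dual attention: parallel position-wise self-attention and channel attention.

Applied to the final backbone feature map (C x H' x W', before global
pooling). The two branches run in parallel and are merged by element-wise
sum:

* Self-attention (SA) is an embedded-Gaussian non-local block: 1x1-conv
  query/key/value projections with a channel bottleneck C/r, a softmax
  attention matrix over the N = H'*W' spatial positions (rows sum to 1),
  and a zero-initialized 1x1 output projection added back to the input
  (residual), so an untrained block is exactly the identity.
* Channel attention (CA) is the cost-efficient one-dimensional-convolution
  form: spatially average each channel to a descriptor d in R^C, convolve
  across channels with a single odd-sized kernel (zero padding, no bias),
  pass through a sigmoid, and gate each channel: out_c = g_c * x_c.

Module forwards operate on batched autodiff tensors (B, C, H, W) so the
branches train end-to-end; the functional wrappers accept plain C x H x W
arrays for single feature maps.
"""

from __future__ import annotations

import numpy as np

from . import _nn
from ._nn import Tensor

__all__ = [
    "SelfAttention2d",
    "ChannelAttention",
    "DualAttention",
    "build_attention",
    "self_attention",
    "channel_attention",
    "dual_attention",
]


class SelfAttention2d(_nn.Module):
    """Embedded-Gaussian non-local block with residual output.

    ratio: bottleneck divisor r; the query/key/value width is max(C // r, 1).
    The output projection starts at zero, so the block initially passes its
    input through unchanged (stable start for fine-tuning).
    """

    def __init__(self, channels: int, ratio: int = 2, *, rng: np.random.Generator):
        super().__init__()
        if channels < 1 or ratio < 1:
            raise ValueError("channels and ratio must be positive")
        self.channels = channels
        self.inner = max(channels // ratio, 1)
        self.query = _nn.Conv2d(channels, self.inner, kernel=1, rng=rng)
        self.key = _nn.Conv2d(channels, self.inner, kernel=1, rng=rng)
        self.value = _nn.Conv2d(channels, self.inner, kernel=1, rng=rng)
        # W_z: zero-initialized so the residual block starts as the identity
        self.lift = _nn.Conv2d(self.inner, channels, kernel=1, rng=rng)
        self.lift.weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        N = H * W
        scale = 1.0 / np.sqrt(self.inner)
        q = self.query(x).reshape(B, self.inner, N).transpose((0, 2, 1))   # B,N,inner
        k = self.key(x).reshape(B, self.inner, N)                          # B,inner,N
        v = self.value(x).reshape(B, self.inner, N)                        # B,inner,N
        scores = (q @ k) * scale                                           # B,N,N
        attn = _nn.softmax(scores, axis=-1)                                # rows sum to 1
        ctx = v @ attn.transpose((0, 2, 1))                                # B,inner,N
        ctx = ctx.reshape(B, self.inner, H, W)
        return x + self.lift(ctx)

    def attention_matrix(self, x: np.ndarray) -> np.ndarray:
        """The N x N row-stochastic attention matrix for one C x H x W map."""
        C, H, W = x.shape
        t = Tensor(x[None])
        N = H * W
        scale = 1.0 / np.sqrt(self.inner)
        q = self.query(t).reshape(1, self.inner, N).transpose((0, 2, 1))
        k = self.key(t).reshape(1, self.inner, N)
        return _nn.softmax((q @ k) * scale, axis=-1).data[0]


class ChannelAttention(_nn.Module):
    """ECA-style gating: sigmoid(conv1d over the channel descriptor)."""

    def __init__(self, kernel: int = 3, *, rng: np.random.Generator):
        super().__init__()
        self.conv = _nn.Conv1dChannel(kernel, rng=rng)
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        desc = x.mean(axis=(2, 3))                       # B,C
        gate = self.conv(desc).sigmoid()                 # B,C in (0,1)
        return x * gate.reshape(B, C, 1, 1)

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Per-channel gates for one C x H x W map."""
        t = Tensor(x[None])
        desc = t.mean(axis=(2, 3))
        return self.conv(desc).sigmoid().data[0]


class DualAttention(_nn.Module):
    """Sum fusion of the SA and CA branch outputs."""

    def __init__(self, channels: int, sa_ratio: int = 2, ca_kernel: int = 3,
                 *, rng: np.random.Generator):
        super().__init__()
        self.sa = SelfAttention2d(channels, ratio=sa_ratio, rng=rng)
        self.ca = ChannelAttention(kernel=ca_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.sa(x) + self.ca(x)


def build_attention(mode: str, channels: int, sa_ratio: int = 2, ca_kernel: int = 3,
                    *, rng: np.random.Generator) -> _nn.Module | None:
    """Attention block for a config mode: none | sa | ca | dual."""
    if mode == "none":
        return None
    if mode == "sa":
        return SelfAttention2d(channels, ratio=sa_ratio, rng=rng)
    if mode == "ca":
        return ChannelAttention(kernel=ca_kernel, rng=rng)
    if mode == "dual":
        return DualAttention(channels, sa_ratio=sa_ratio, ca_kernel=ca_kernel, rng=rng)
    raise ValueError(f"unknown attention mode {mode!r}")


def _apply_single(module: _nn.Module, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("feature map must be C x H x W")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature map")
    module.eval()
    return module(Tensor(x[None])).data[0]


def self_attention(x: np.ndarray, params: SelfAttention2d) -> np.ndarray:
    """Apply one SA block to a C x H x W map (functional form)."""
    return _apply_single(params, x)


def channel_attention(x: np.ndarray, params: ChannelAttention) -> np.ndarray:
    """Apply one CA block to a C x H x W map (functional form)."""
    return _apply_single(params, x)


def dual_attention(x: np.ndarray, params: DualAttention) -> np.ndarray:
    """SA(x) + CA(x) for a single C x H x W map."""
    return _apply_single(params, x)
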