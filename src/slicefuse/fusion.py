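"""3D-to-2D slice pooling: learnable weighted pooling and fixed baselines.

Learnable weighted pooling (LWP) scores every slice I_x of a T-slice stack
with a small shared-weight CNN (the slice network psi), normalizes the
scalar scores Q_x = psi(I_x) with a softmax,

    alpha_x = exp(Q_x) / sum_x' exp(Q_x'),

and fuses the stack into one 2D image as the convex combination
F = sum_x alpha_x * I_x. Because the weights come from a network that is
trained end-to-end with the classifier, the model learns *which slices
matter* for the diagnosis.

The fixed baselines are pixel-wise max, pixel-wise average, and approximate
rank pooling (ARP), whose plain coefficients depend only on slice index and
count: alpha_t = 2t - T - 1 for t = 1..T (they sum to zero, so a constant
stack fuses to the all-zero image). The ``time_averaged`` ARP variant first
replaces each slice with its running mean (1/t) * sum_{tau<=t} I_tau and
then applies the plain coefficients; expanded per original slice tau this
gives c_tau = sum_{t>=tau} (2t - T - 1)/t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor
from .volume_io import SliceStack, ViewAxis

__all__ = [
    "SliceNetwork",
    "SliceWeights",
    "FusedImage",
    "init_slice_network",
    "slice_logits",
    "normalize_weights",
    "fuse_lwp",
    "arp_weights",
    "fuse_arp",
    "fuse_max",
    "fuse_avg",
    "fuse",
]

DEFAULT_CHANNEL_PLAN = (8, 16, 32, 64)


@dataclass
class SliceWeights:
    """Per-slice raw logits Q and their softmax-normalized weights alpha."""

    logits: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if self.logits.shape != self.weights.shape:
            raise ValueError("logits and weights must have equal length")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite slice weights")


@dataclass
class FusedImage:
    """A 2D H x W fusion of a slice stack, tagged with method and view."""

    pixels: np.ndarray
    method: str
    view: ViewAxis | None = None

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("fused image must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixels in fused image")


class SliceNetwork(_nn.Module):
    """Shared-weight scoring CNN psi: one scalar logit per 2D slice.

    Four 3x3 stride-2 convolutions (ReLU after each), global average
    pooling, and a linear projection to a single scalar. Fully
    convolutional, so any H x W slice size is accepted. Kaiming-initialized
    and reproducible from the seed.
    """

    def __init__(self, seed: int, channel_plan=DEFAULT_CHANNEL_PLAN):
        super().__init__()
        channel_plan = tuple(int(c) for c in channel_plan)
        if len(channel_plan) != 4:
            raise ValueError("channel_plan must list 4 stage widths")
        if any(c < 1 for c in channel_plan):
            raise ValueError("channel widths must be positive")
        rng = np.random.default_rng(seed)
        self.channel_plan = channel_plan
        self.seed = seed
        widths = (1,) + channel_plan
        self.convs = [
            _nn.Conv2d(widths[i], widths[i + 1], kernel=3, stride=2, padding=1, rng=rng)
            for i in range(4)
        ]
        self.gap = _nn.GlobalAvgPool2d()
        self.head = _nn.Linear(channel_plan[-1], 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(B, 1, H, W) slices -> (B,) logits."""
        for conv in self.convs:
            x = conv(x).relu()
        feat = self.gap(x)
        return self.head(feat).reshape(x.shape[0])


def init_slice_network(seed: int, channel_plan=DEFAULT_CHANNEL_PLAN) -> SliceNetwork:
    """Build a seeded slice network; identical seeds give identical weights."""
    return SliceNetwork(seed=seed, channel_plan=channel_plan)


def _stack_array(stack: SliceStack | np.ndarray) -> np.ndarray:
    arr = stack.slices if isinstance(stack, SliceStack) else np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("slice stack must be a non-empty T x H x W array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite voxels in slice stack")
    return arr


def _view_of(stack) -> ViewAxis | None:
    return stack.view if isinstance(stack, SliceStack) else None


def slice_logits(stack: SliceStack | np.ndarray, network: SliceNetwork) -> np.ndarray:
    """Score each slice with the shared network: returns Q, length T."""
    arr = _stack_array(stack)
    network.eval()
    out = network(Tensor(arr[:, None, :, :]))
    q = out.data
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite slice logits")
    return q


def normalize_weights(q: np.ndarray) -> np.ndarray:
    """Stable softmax over slice logits; returns alpha with sum 1."""
    q = np.asarray(q, dtype=np.float64)
    if q.size == 0:
        raise ValueError("empty logit vector")
    z = np.exp(q - q.max())
    return z / z.sum()


def fuse_lwp(stack: SliceStack | np.ndarray, alpha: np.ndarray) -> FusedImage:
    """F = sum_x alpha_x * I_x — a convex combination of the slices."""
    arr = _stack_array(stack)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != (arr.shape[0],):
        raise ValueError(f"weight length {alpha.shape} does not match T={arr.shape[0]}")
    if np.any(alpha < 0) or not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise ValueError("alpha must be a probability vector")
    pixels = np.tensordot(alpha, arr, axes=(0, 0))
    return FusedImage(pixels=pixels, method="lwp", view=_view_of(stack))


def arp_weights(T: int, variant: str = "plain") -> np.ndarray:
    """Approximate-rank-pooling coefficients for a stack of T slices.

    plain: alpha_t = 2t - T - 1 (t = 1..T). time_averaged: the per-slice
    coefficients induced by applying the plain weights to running means,
    c_tau = sum_{t=tau}^{T} (2t - T - 1)/t.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(1, T + 1, dtype=np.float64)
    plain = 2.0 * t - T - 1.0
    if variant == "plain":
        return plain
    if variant == "time_averaged":
        ratio = plain / t
        # suffix sums: coefficient of slice tau collects every t >= tau
        return np.cumsum(ratio[::-1])[::-1].copy()
    raise ValueError(f"unknown ARP variant {variant!r}")


def fuse_arp(stack: SliceStack | np.ndarray, variant: str = "plain") -> FusedImage:
    arr = _stack_array(stack)
    w = arp_weights(arr.shape[0], variant)
    pixels = np.tensordot(w, arr, axes=(0, 0))
    return FusedImage(pixels=pixels, method="arp", view=_view_of(stack))


def fuse_max(stack: SliceStack | np.ndarray) -> FusedImage:
    arr = _stack_array(stack)
    return FusedImage(pixels=arr.max(axis=0), method="max", view=_view_of(stack))


def fuse_avg(stack: SliceStack | np.ndarray) -> FusedImage:
    arr = _stack_array(stack)
    return FusedImage(pixels=arr.mean(axis=0), method="avg", view=_view_of(stack))


def fuse(stack: SliceStack | np.ndarray, method: str,
         network: SliceNetwork | None = None, arp_variant: str = "plain") -> FusedImage:
    """Dispatch to one pooling operator by name."""
    if method == "lwp":
        if network is None:
            raise ValueError("lwp fusion requires a slice network")
        alpha = normalize_weights(slice_logits(stack, network))
        return fuse_lwp(stack, alpha)
    if method == "arp":
        return fuse_arp(stack, arp_variant)
    if method == "max":
        return fuse_max(stack)
    if method == "avg":
        return fuse_avg(stack)
    raise ValueError(f"unknown pooling method {method!r}")
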