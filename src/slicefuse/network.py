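"""End-to-end model assembly: slice network -> fusion -> 2D backbone ->
attention -> classifier, plus analytic multiply-add (MADs) accounting.

The pipeline classifies one 3D volume by (1) reorienting it so the chosen
view is the fusion axis, (2) collapsing the T slices to a single 2D image
with the configured pooling operator (learnable weighted pooling or a fixed
baseline), (3) replicating the single channel to three so a standard 2D
feature extractor applies, (4) refining the final feature map with the
optional attention block, and (5) classifying via global average pooling and
a three-layer fully connected head (widths 512, 64, 2; batch normalization
and dropout after the first two layers, dropout probability 0.5).

Backbones available in this build: ``tiny`` (a 4-stage CNN for desk-scale
experiments and tests), ``resnet34`` and ``vgg11`` (full architectures,
randomly initialized). Pretrained ImageNet weights are not bundled, so
``pretrained=True`` raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor
from .attention import build_attention
from .fusion import SliceNetwork, DEFAULT_CHANNEL_PLAN, arp_weights
from .volume_io import VolumeSample, ViewAxis, reorient_for_view, normalize_volume

__all__ = [
    "ModelConfig",
    "LWPModel",
    "build_model",
    "adapt_input",
    "forward",
    "forward_batch",
    "slice_weights",
    "count_mads",
    "save_checkpoint",
    "load_checkpoint",
    "prepare_stack",
]

POOLING_METHODS = ("lwp", "arp", "max", "avg")
ATTENTION_MODES = ("none", "sa", "ca", "dual")
BACKBONES = ("tiny", "resnet34", "vgg11", "densenet121", "mobilenet_v2", "efficientnet")
_UNAVAILABLE_BACKBONES = ("densenet121", "mobilenet_v2", "efficientnet")


@dataclass
class ModelConfig:
    """Everything needed to rebuild a model deterministically (plus a seed)."""

    backbone_id: str = "tiny"
    pretrained: bool = False
    pooling: str = "lwp"
    view: str = "axial"
    attention_mode: str = "none"
    dropout_p: float = 0.5
    classifier_dims: tuple[int, int, int] = (512, 64, 2)
    slice_channels: tuple[int, ...] = DEFAULT_CHANNEL_PLAN
    sa_ratio: int = 2
    ca_kernel: int = 3
    arp_variant: str = "plain"
    normalization: str = "minmax"

    def __post_init__(self):
        if self.backbone_id not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone_id!r}; choose from {BACKBONES}")
        if self.pooling not in POOLING_METHODS:
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(f"unknown attention mode {self.attention_mode!r}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.classifier_dims[-1] != 2:
            raise ValueError("classifier must end in 2 logits (binary diagnosis)")


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------


class TinyBackbone(_nn.Module):
    """Four 3x3 stride-2 conv stages (16, 32, 64, 128) with ReLU.

    Small enough that a full cross-validated training run on phantom volumes
    takes minutes on one CPU; feature width 128.
    """

    feature_width = 128

    def __init__(self, *, rng: np.random.Generator):
        super().__init__()
        widths = (3, 16, 32, 64, 128)
        self.stages = [
            _nn.Conv2d(widths[i], widths[i + 1], kernel=3, stride=2, padding=1, rng=rng)
            for i in range(4)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.stages:
            x = conv(x).relu()
        return x


class _BasicBlock(_nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng):
        super().__init__()
        self.conv1 = _nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = _nn.BatchNorm2d(out_ch)
        self.conv2 = _nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = _nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = _nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = _nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + shortcut).relu()


class ResNet34Backbone(_nn.Module):
    """Standard ResNet-34 feature extractor (random initialization)."""

    feature_width = 512

    def __init__(self, *, rng: np.random.Generator):
        super().__init__()
        self.stem = _nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = _nn.BatchNorm2d(64)
        self.pool = _nn.MaxPool2d(3, stride=2, padding=1)
        plan = [(64, 64, 3, 1), (64, 128, 4, 2), (128, 256, 6, 2), (256, 512, 3, 2)]
        self.blocks: list[_BasicBlock] = []
        for in_ch, out_ch, n, stride in plan:
            self.blocks.append(_BasicBlock(in_ch, out_ch, stride, rng=rng))
            for _ in range(n - 1):
                self.blocks.append(_BasicBlock(out_ch, out_ch, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.stem_bn(self.stem(x)).relu())
        for block in self.blocks:
            x = block(x)
        return x


class VGG11Backbone(_nn.Module):
    """VGG-11 convolutional stages (random initialization)."""

    feature_width = 512

    def __init__(self, *, rng: np.random.Generator):
        super().__init__()
        cfg = [64, "M", 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"]
        layers: list[_nn.Module] = []
        in_ch = 3
        for item in cfg:
            if item == "M":
                layers.append(_nn.MaxPool2d(2, stride=2))
            else:
                layers.append(_nn.Conv2d(in_ch, int(item), 3, padding=1, rng=rng))
                layers.append(_nn.ReLU())
                in_ch = int(item)
        self.features = _nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.features(x)


def _make_backbone(backbone_id: str, pretrained: bool, rng: np.random.Generator) -> _nn.Module:
    if backbone_id in _UNAVAILABLE_BACKBONES:
        raise ValueError(
            f"backbone {backbone_id!r} is not available in this build; "
            f"use one of ('tiny', 'resnet34', 'vgg11')"
        )
    if pretrained:
        raise ValueError(
            "pretrained weights are not bundled with this package; "
            "build with pretrained=False or load a checkpoint"
        )
    return {"tiny": TinyBackbone, "resnet34": ResNet34Backbone,
            "vgg11": VGG11Backbone}[backbone_id](rng=rng)


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------


class LWPModel(_nn.Module):
    """Slice network + pooling + backbone + attention + FC classifier."""

    def __init__(self, config: ModelConfig, seed: int):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        # always consume the slice-net seed so the downstream parameter draws
        # are identical across pooling choices at a fixed model seed
        slice_seed = int(rng.integers(2**31))
        self.slice_net = (SliceNetwork(seed=slice_seed, channel_plan=config.slice_channels)
                          if config.pooling == "lwp" else None)
        self.backbone = _make_backbone(config.backbone_id, config.pretrained, rng)
        C = self.backbone.feature_width
        self.attention = build_attention(config.attention_mode, C,
                                         sa_ratio=config.sa_ratio,
                                         ca_kernel=config.ca_kernel, rng=rng)
        self.gap = _nn.GlobalAvgPool2d()
        d1, d2, d3 = config.classifier_dims
        # classifier weights are always randomly initialized
        self.fc1 = _nn.Linear(C, d1, rng=rng)
        self.bn1 = _nn.BatchNorm1d(d1)
        self.drop1 = _nn.Dropout(config.dropout_p, rng=rng)
        self.fc2 = _nn.Linear(d1, d2, rng=rng)
        self.bn2 = _nn.BatchNorm1d(d2)
        self.drop2 = _nn.Dropout(config.dropout_p, rng=rng)
        self.fc3 = _nn.Linear(d2, d3, rng=rng)

    # fusion ---------------------------------------------------------------

    def fuse_batch(self, stacks: Tensor) -> tuple[Tensor, Tensor | None]:
        """(B, T, H, W) stacks -> (B, H, W) fused images and alpha (B, T) for LWP."""
        B, T, H, W = stacks.shape
        if self.config.pooling == "lwp":
            flat = stacks.reshape(B * T, 1, H, W)
            logits = self.slice_net(flat).reshape(B, T)
            alpha = _nn.softmax(logits, axis=1)
            fused = (stacks * alpha.reshape(B, T, 1, 1)).sum(axis=1)
            return fused, alpha
        if self.config.pooling == "avg":
            return stacks.mean(axis=1), None
        if self.config.pooling == "max":
            return stacks.max(axis=1), None
        w = Tensor(arp_weights(T, self.config.arp_variant).reshape(1, T, 1, 1))
        return (stacks * w).sum(axis=1), None

    # full pipeline ---------------------------------------------------------

    def forward(self, stacks: Tensor) -> Tensor:
        """(B, T, H, W) reoriented stacks -> (B, 2) class logits."""
        fused, _ = self.fuse_batch(stacks)
        B, H, W = fused.shape
        img = fused.reshape(B, 1, H, W) * Tensor(np.ones((1, 3, 1, 1)))  # 3-channel replicate
        feat = self.backbone(img)
        if self.attention is not None:
            feat = self.attention(feat)
        h = self.gap(feat)
        h = self.drop1(self.bn1(self.fc1(h)).relu())
        h = self.drop2(self.bn2(self.fc2(h)).relu())
        return self.fc3(h)

    def predict_proba(self, stacks: np.ndarray) -> np.ndarray:
        """(B, T, H, W) -> (B, 2) class probabilities, eval mode."""
        was_training = self.training
        self.eval()
        probs = _nn.softmax(self.forward(Tensor(stacks)), axis=1).data
        if was_training:
            self.train()
        return probs


def build_model(config: ModelConfig, seed: int) -> LWPModel:
    """Deterministically build a model from its config and seed."""
    return LWPModel(config, seed)


def adapt_input(fused: np.ndarray) -> np.ndarray:
    """Replicate a 2D single-channel image to 3 identical channels."""
    fused = np.asarray(fused, dtype=np.float64)
    if fused.ndim != 2:
        raise ValueError("adapt_input expects a 2D image")
    return np.repeat(fused[None], 3, axis=0)


def prepare_stack(v: VolumeSample, config: ModelConfig) -> np.ndarray:
    """Normalize and reorient one volume into the model's (T, H, W) layout."""
    if config.normalization != "none":
        v = normalize_volume(v, config.normalization)
    return reorient_for_view(v, config.view).slices


def forward(model: LWPModel, v: VolumeSample) -> np.ndarray:
    """Classify one volume: returns the 2-vector of class probabilities."""
    stack = prepare_stack(v, model.config)
    return model.predict_proba(stack[None])[0]


def forward_batch(model: LWPModel, volumes: list[VolumeSample]) -> np.ndarray:
    stacks = np.stack([prepare_stack(v, model.config) for v in volumes])
    return model.predict_proba(stacks)


def slice_weights(model: LWPModel, v: VolumeSample):
    """Per-slice logits and softmax weights of one volume under an LWP model."""
    from .fusion import SliceWeights, normalize_weights, slice_logits

    if model.slice_net is None:
        raise ValueError("slice weights are only defined for pooling='lwp'")
    stack = prepare_stack(v, model.config)
    q = slice_logits(stack, model.slice_net)
    return SliceWeights(logits=q, weights=normalize_weights(q))


def count_mads(model: LWPModel, input_shape: tuple[int, int, int]) -> int:
    """Analytic multiply-adds of one forward pass on a (T, H, W) volume.

    Convolutions contribute k_h*k_w*C_in*C_out*H_out*W_out, linear layers and
    attention matmuls their inner-product volume; parameter-free poolings and
    normalizations contribute 0. Counted by instrumenting an actual forward
    pass, so the number always matches the executed architecture.
    """
    stacks = np.zeros((1, *input_shape))
    was_training = model.training
    model.eval()
    with _nn.mad_counter() as acc:
        model.forward(Tensor(stacks))
    if was_training:
        model.train()
    return acc[0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: LWPModel, path: str | Path) -> Path:
    """Serialize config, seed and all parameter/running-stat arrays (.npz)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    cfg = asdict(model.config)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(json.dumps({"config": cfg, "seed": model.seed})),
             **arrays)
    return path


def load_checkpoint(path: str | Path) -> LWPModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg = meta["config"]
    for key in ("classifier_dims", "slice_channels"):
        cfg[key] = tuple(cfg[key])
    model = LWPModel(ModelConfig(**cfg), seed=meta["seed"])
    model.load_state_arrays(arrays)
    return model
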