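"""The fully convolutional counter.

Three pieces: a staged backbone tapped at output strides 8/16/32, a top-down
multilayer fusion decoder, and a redundant classification head that scores
count-interval classes for overlapping 32x32 patches.

Each fusion step projects the deeper (semantically stronger) map to twice the
channel width of the shallower map, upsamples it bilinearly, concatenates the
shallower map, and reduces back with a 1x1 convolution — so high-level
semantics dominate the fused representation (2/3 of the channels before
reduction) and low-level detail plays a supporting role. Fusing 1, 2 or 3
taps leaves the output at stride 32, 16 or 8 respectively.

The head mirrors redundant patch sampling: unpadded average pooling whose
kernel spans 32 input pixels at the fused stride, followed by a 1x1
convolution to class logits. For a stride-8 fused map that is a 4x4 pool at
stride 1, giving one cell per 32x32 input patch at stride 8, so the logit
grid for an HxW input (divisible by 32) is (H/8 - 3) x (W/8 - 3).

Two backbones are provided: ``tiny``, a small plain-conv pyramid meant for
CPU-scale experiments and tests, and ``mixnet``, a mixed-kernel depthwise
(MDConv) architecture in the MixNet family. Weights initialize with the
Xavier scheme; a checkpoint or an ``.npz`` of named arrays can be loaded on
top.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path

import numpy as np

from . import nnkit as nn
from .codec import ClassMap, PatchGrid, QuantizerSpec

__all__ = [
    "BackboneSpec",
    "build_backbone",
    "FuseStep",
    "FusionDecoder",
    "RedundantHead",
    "CountingNetwork",
    "predict_class_map",
    "save_checkpoint",
    "load_checkpoint",
    "PATCH_SIZE",
]

PATCH_SIZE = 32  # redundant sampling patch side, in input pixels


@dataclass(frozen=True)
class BackboneSpec:
    """Which feature extractor to build and where to tap it.

    ``stage_strides`` are the output strides of the tapped stages (strictly
    increasing); ``stage_channels`` the channel widths at those taps.
    ``pretrained_weights`` optionally names an ``.npz`` of named arrays to
    load by name/shape match.
    """

    name: str = "tiny"
    stage_strides: tuple[int, ...] = (8, 16, 32)
    stage_channels: tuple[int, ...] = ()
    pretrained_weights: str | None = None

    def __post_init__(self):
        if list(self.stage_strides) != sorted(set(self.stage_strides)):
            raise ValueError("stage_strides must be strictly increasing")
        if not self.stage_channels:
            defaults = {"tiny": (32, 48, 64), "mixnet": (56, 104, 264)}
            if self.name not in defaults:
                raise ValueError(f"unknown backbone '{self.name}'")
            object.__setattr__(self, "stage_channels", defaults[self.name])
        if len(self.stage_channels) != len(self.stage_strides):
            raise ValueError("one channel width per tap required")


def _conv_bn_act(cin, cout, k, stride, rng, act=nn.ReLU):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        act(),
    )


class TinyBackbone(nn.Module):
    """Small plain-convolution pyramid with taps at strides 8/16/32.

    Sized for single-CPU training on synthetic scenes; not intended to be
    competitive on real field imagery.
    """

    def __init__(self, channels=(32, 48, 64), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c8, c16, c32 = channels
        self.stem = _conv_bn_act(3, 20, 5, 4, rng)
        self.stage8 = nn.Sequential(
            _conv_bn_act(20, c8, 3, 2, rng),
            _conv_bn_act(c8, c8, 3, 1, rng),
        )
        self.stage16 = _conv_bn_act(c8, c16, 3, 2, rng)
        self.stage32 = _conv_bn_act(c16, c32, 3, 2, rng)

    def forward(self, x):
        x = self.stem(x)
        f8 = self.stage8(x)
        f16 = self.stage16(f8)
        f32 = self.stage32(f16)
        return [f8, f16, f32]


class MDConvBlock(nn.Module):
    """Inverted-residual block with a mixed-kernel depthwise convolution.

    The expanded channels are split into groups convolved with kernels
    3, 5, 7, ... so one block sees several receptive-field sizes at once.
    """

    def __init__(self, cin, cout, stride, expand, kernels=(3, 5, 7), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = cin * expand
        self.expand = _conv_bn_act(cin, mid, 1, 1, rng, act=nn.Swish) if expand > 1 else None
        # channel split for the mixed depthwise conv; remainder to the first group
        base = mid // len(kernels)
        self.splits = [base + (mid - base * len(kernels) if i == 0 else 0) for i in range(len(kernels))]
        self.dw = [
            nn.Conv2d(c, c, k, stride=stride, padding=k // 2, groups=c, bias=False, rng=rng)
            for c, k in zip(self.splits, kernels)
        ]
        self.dw_bn = nn.BatchNorm2d(mid)
        self.act = nn.Swish()
        self.project = nn.Sequential(
            nn.Conv2d(mid, cout, 1, bias=False, rng=rng), nn.BatchNorm2d(cout)
        )
        self.residual = stride == 1 and cin == cout

    def forward(self, x):
        h = self.expand(x) if self.expand is not None else x
        offs = np.cumsum([0] + self.splits)
        parts = []
        for i, conv in enumerate(self.dw):
            chunk = nn.Tensor(h.data[:, offs[i] : offs[i + 1]], _parents=(h,),
                              _grad_fn=None)
            # slicing with autodiff: route gradient back by padding zeros
            lo, hi = int(offs[i]), int(offs[i + 1])

            def make_grad(lo=lo, hi=hi):
                def grad_fn(g):
                    gh = np.zeros_like(h.data)
                    gh[:, lo:hi] = g
                    return (gh,)
                return grad_fn

            chunk._grad_fn = make_grad()
            parts.append(conv(chunk))
        h = self.act(self.dw_bn(nn.concat(parts, axis=1)))
        h = self.project(h)
        if self.residual:
            h = nn.add(h, x)
        return h


class MixNetBackbone(nn.Module):
    """Mixed-kernel depthwise backbone (MixNet family), tapped at 8/16/32."""

    def __init__(self, channels=(56, 104, 264), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c8, c16, c32 = channels
        self.stem = _conv_bn_act(3, 24, 3, 2, rng, act=nn.Swish)
        self.stage4 = MDConvBlock(24, 32, stride=2, expand=3, kernels=(3, 5), rng=rng)
        self.stage8 = nn.Sequential(
            MDConvBlock(32, c8, stride=2, expand=3, rng=rng),
            MDConvBlock(c8, c8, stride=1, expand=3, rng=rng),
        )
        self.stage16 = nn.Sequential(
            MDConvBlock(c8, c16, stride=2, expand=3, rng=rng),
            MDConvBlock(c16, c16, stride=1, expand=3, rng=rng),
        )
        self.stage32 = nn.Sequential(
            MDConvBlock(c16, c32, stride=2, expand=3, rng=rng),
            MDConvBlock(c32, c32, stride=1, expand=3, rng=rng),
        )

    def forward(self, x):
        x = self.stage4(self.stem(x))
        f8 = self.stage8(x)
        f16 = self.stage16(f8)
        f32 = self.stage32(f16)
        return [f8, f16, f32]


def build_backbone(spec: BackboneSpec, rng: np.random.Generator | None = None) -> nn.Module:
    if spec.name == "tiny":
        bb = TinyBackbone(spec.stage_channels, rng=rng)
    elif spec.name == "mixnet":
        bb = MixNetBackbone(spec.stage_channels, rng=rng)
    else:
        raise ValueError(f"unknown backbone '{spec.name}'")
    if spec.pretrained_weights:
        state = dict(np.load(spec.pretrained_weights))
        bb.load_state_dict(state, strict=False)
    return bb


def extract_features(image: np.ndarray, backbone: nn.Module, spec: BackboneSpec):
    """Run the backbone on an NCHW batch, checking divisibility first."""
    x = nn.Tensor(image)
    max_stride = max(spec.stage_strides)
    h, w = x.data.shape[2], x.data.shape[3]
    if h % max_stride or w % max_stride:
        raise ValueError(
            f"input dims {(h, w)} not divisible by {max_stride}; pad the image first"
        )
    return backbone(x)


class FuseStep(nn.Module):
    """One top-down fusion step.

    The deeper map (C1 x H1 x W1) is projected to 2*C2 channels, batch
    normalized, bilinearly upsampled to 2H1 x 2W1, concatenated with the
    shallower map (C2 channels), and reduced by a 1x1 convolution back to
    2*C2 — so the output honors the 2H1 x 2W1 x 2C2 contract while the
    deeper features keep the channel majority.
    """

    def __init__(self, c_high: int, c_low: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.proj = nn.Conv2d(c_high, 2 * c_low, 1, bias=False, rng=rng)
        self.proj_bn = nn.BatchNorm2d(2 * c_low)
        self.reduce = nn.Conv2d(3 * c_low, 2 * c_low, 1, bias=False, rng=rng)
        self.reduce_bn = nn.BatchNorm2d(2 * c_low)
        self.out_channels = 2 * c_low

    def forward(self, high, low):
        if (low.data.shape[2], low.data.shape[3]) != (2 * high.data.shape[2], 2 * high.data.shape[3]):
            raise ValueError(
                f"fuse_step: low dims {low.data.shape[2:]} must be exactly twice "
                f"high dims {high.data.shape[2:]}"
            )
        up = nn.upsample_bilinear2x(self.proj_bn(self.proj(high)))
        cat = nn.concat([up, low], axis=1)
        return nn.relu(self.reduce_bn(self.reduce(cat)))


class FusionDecoder(nn.Module):
    """Iterated fusion from the deepest tap downward.

    ``n_layers=1`` passes the deepest map through; each extra layer fuses the
    next shallower tap, halving the output stride.
    """

    def __init__(self, tap_channels, tap_strides, n_layers: int, rng=None):
        super().__init__()
        if not 1 <= n_layers <= len(tap_channels):
            raise ValueError(f"n_layers must be in [1, {len(tap_channels)}], got {n_layers}")
        self.n_layers = n_layers
        self.out_stride = tap_strides[len(tap_strides) - n_layers]
        steps = []
        c = tap_channels[-1]
        for k in range(n_layers - 1):
            low_c = tap_channels[-2 - k]
            steps.append(FuseStep(c, low_c, rng=rng))
            c = steps[-1].out_channels
        self.steps = steps
        self.out_channels = c

    def forward(self, pyramid):
        f = pyramid[-1]
        for k, step in enumerate(self.steps):
            f = step(f, pyramid[-2 - k])
        return f


class RedundantHead(nn.Module):
    """Average pooling + 1x1 class projection over overlapping patches.

    The pool kernel is ``PATCH_SIZE / feature_stride`` at stride 1 and
    unpadded, so each output cell scores one 32x32 input patch and the patch
    stride equals the fused feature stride. ``n_out`` is the number of count
    classes, or 1 for the local-count regression ablation.
    """

    def __init__(self, in_channels: int, n_out: int, feature_stride: int = 8, rng=None):
        super().__init__()
        if PATCH_SIZE % feature_stride:
            raise ValueError(f"feature stride {feature_stride} must divide {PATCH_SIZE}")
        self.pool = PATCH_SIZE // feature_stride
        self.feature_stride = feature_stride
        self.classify = nn.Conv2d(in_channels, n_out, 1, rng=rng)

    def forward(self, fused):
        h, w = fused.data.shape[2], fused.data.shape[3]
        if h < self.pool or w < self.pool:
            raise ValueError(f"fused map {(h, w)} smaller than pool kernel {self.pool}")
        pooled = nn.avg_pool2d(fused, self.pool, stride=1) if self.pool > 1 else fused
        return self.classify(pooled)


class CountingNetwork(nn.Module):
    """Backbone + fusion decoder + redundant head, with codec metadata.

    ``mode`` selects the blockwise-classification head (count-interval logits)
    or the local-count regression ablation (a single linear output per patch).
    The quantizer spec and input normalization statistics travel with the
    model so a checkpoint is self-describing.
    """

    def __init__(
        self,
        backbone_spec: BackboneSpec = BackboneSpec(),
        n_layers: int = 3,
        quantizer: QuantizerSpec = QuantizerSpec(),
        mode: str = "classification",
        sigma: float = 4.0,
        norm_mean=(0.0, 0.0, 0.0),
        norm_std=(1.0, 1.0, 1.0),
        downsample_ratio: float = 1.0,
        seed: int = 0,
    ):
        super().__init__()
        if mode not in ("classification", "regression"):
            raise ValueError(f"mode must be classification or regression, got '{mode}'")
        rng = np.random.default_rng(seed)
        self.backbone_spec = backbone_spec
        self.n_layers = n_layers
        self.quantizer = quantizer
        self.mode = mode
        self.sigma = sigma
        self.norm_mean = np.asarray(norm_mean, dtype=np.float32)
        self.norm_std = np.asarray(norm_std, dtype=np.float32)
        self.downsample_ratio = downsample_ratio
        self.seed = seed
        self.backbone = build_backbone(backbone_spec, rng=rng)
        self.fusion = FusionDecoder(
            backbone_spec.stage_channels, backbone_spec.stage_strides, n_layers, rng=rng
        )
        n_out = quantizer.n_classes if mode == "classification" else 1
        self.head = RedundantHead(self.fusion.out_channels, n_out, self.fusion.out_stride, rng=rng)

    @property
    def patch_stride(self) -> int:
        return self.fusion.out_stride

    def forward(self, x):
        """NCHW batch -> per-patch logits (classification) or counts (regression)."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        pyramid = self.backbone(x)
        fused = self.fusion(pyramid)
        return self.head(fused)

    def config(self) -> dict:
        return {
            "backbone_spec": asdict(self.backbone_spec),
            "n_layers": self.n_layers,
            "quantizer": asdict(self.quantizer),
            "mode": self.mode,
            "sigma": self.sigma,
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "downsample_ratio": self.downsample_ratio,
            "seed": self.seed,
        }


def class_probabilities(logits: np.ndarray) -> np.ndarray:
    """Softmax over the class axis of an (N, C, H, W) logit map."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def predict_class_map(
    probs: np.ndarray, image_shape: tuple[int, int], spec: QuantizerSpec, patch_stride: int = 8
) -> ClassMap:
    """Per-cell argmax of a (C, H, W) probability (or logit) map.

    np.argmax returns the first maximum, so ties break toward the lower class
    index, keeping outputs deterministic.
    """
    values = probs.argmax(axis=0)
    grid = PatchGrid(block=PATCH_SIZE, stride=patch_stride, image_shape=image_shape)
    if values.shape != grid.n_patches:
        raise ValueError(f"probability grid {values.shape} != patch grid {grid.n_patches}")
    return ClassMap(values=values.astype(np.int64), grid=grid, spec=spec)


def save_checkpoint(model: CountingNetwork, path: str | Path):
    """Single-archive checkpoint: weights npz + JSON metadata block."""
    path = Path(path)
    buf = BytesIO()
    np.savez(buf, **model.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(model.config(), indent=1))


def load_checkpoint(path: str | Path) -> CountingNetwork:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        state = dict(np.load(BytesIO(zf.read("weights.npz"))))
    bs = meta.pop("backbone_spec")
    bs["stage_strides"] = tuple(bs["stage_strides"])
    bs["stage_channels"] = tuple(bs["stage_channels"])
    bs.pop("pretrained_weights", None)
    q = meta.pop("quantizer")
    model = CountingNetwork(
        backbone_spec=BackboneSpec(**bs),
        quantizer=QuantizerSpec(**q),
        **meta,
    )
    model.load_state_dict(state)
    return model
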