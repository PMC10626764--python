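"""Encoder–decoder segmentation backbones with auxiliary HOG-regression heads.

Two backbones are provided:

* **UNet** — the classic contracting/expanding architecture with skip
  connections; one auxiliary head sits on the bottleneck.
* **U2Net** — a nested-U ("UNet inside UNet") architecture built from
  residual U-blocks (RSU), with deep-supervision side outputs fused by a
  1×1 convolution; one auxiliary head sits on every decoder stage plus the
  bottom stage.

Each auxiliary head regresses the image's HOG pseudo-label: a 1×1 adapter
convolution reduces the incoming feature map to 3 channels, then two
(3×3 conv → ReLU → 2×2 max-pool) stages keep 3 channels while quartering the
spatial size, and a final linear map emits the D-dimensional descriptor.
Because decoder feature maps are generally rectangular and vary with the
input size, the head resizes the pooled map to its reference spatial size
before flattening, so the output length is always D.

Channel widths scale with ``width_scale`` so that desk-scale configurations
train in seconds on one CPU while the default plan matches the standard
UNet/U2Net channel progressions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor


class ModelConfigError(ValueError):
    """Raised for inconsistent model specifications."""


_PLACEMENTS = ("bottleneck_only", "all_decoder_stages", "none")


@dataclasses.dataclass(frozen=True)
class MultiTaskModelSpec:
    """Backbone choice, head placement and scaling knobs.

    ``input_size`` is (width, height); ``hog_dim`` must equal the descriptor
    length of the HOG configuration used to build the pseudo-labels.
    ``head_placement=None`` picks the per-backbone default: bottleneck only
    for UNet, one head per decoder stage (incl. the bottom) for U2Net;
    ``"none"`` builds the plain single-task backbone.
    """

    backbone: str = "unet"
    n_classes: int = 6
    input_size: tuple[int, int] = (64, 128)
    hog_dim: int = 504
    head_placement: str | None = None
    width_scale: float = 1.0
    n_stages: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("unet", "u2net"):
            raise ModelConfigError(f"unknown backbone {self.backbone!r}")
        if self.hog_dim <= 0 and self.resolved_placement != "none":
            raise ModelConfigError(f"hog_dim must be positive, got {self.hog_dim}")
        if self.n_classes <= 0:
            raise ModelConfigError("n_classes must be positive")
        if self.head_placement is not None and self.head_placement not in _PLACEMENTS:
            raise ModelConfigError(f"unknown head_placement {self.head_placement!r}")
        if self.width_scale <= 0:
            raise ModelConfigError("width_scale must be positive")

    @property
    def resolved_placement(self) -> str:
        if self.head_placement is not None:
            return self.head_placement
        return "bottleneck_only" if self.backbone == "unet" else "all_decoder_stages"

    @property
    def resolved_stages(self) -> int:
        if self.n_stages is not None:
            if self.n_stages < 2:
                raise ModelConfigError("n_stages must be >= 2")
            return self.n_stages
        return 5 if self.backbone == "unet" else 6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MultiTaskModelSpec":
        d = dict(d)
        if "input_size" in d:
            d["input_size"] = tuple(d["input_size"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class AuxHeadSpec:
    """Structure of one auxiliary regression unit."""

    in_channels: int
    spatial: tuple[int, int]  # (h, w) reference feature-map size at build
    out_dim: int

    @property
    def pooled(self) -> tuple[int, int]:
        h, w = self.spatial
        return (-(-h // 4), -(-w // 4))  # two ceil-mode 2x2 pools

    @property
    def flatten_size(self) -> int:
        ph, pw = self.pooled
        return 3 * ph * pw


@dataclasses.dataclass
class MultiTaskOutput:
    """Forward-pass result: segmentation logits and per-head HOG predictions.

    ``seg_logits`` is the primary full-resolution class-score map; for U2Net
    ``side_logits`` additionally carries the deep-supervision side maps
    (each already upsampled to the input resolution).
    """

    seg_logits: Tensor
    hog_preds: list[Tensor]
    side_logits: list[Tensor] = dataclasses.field(default_factory=list)

    @property
    def all_seg_maps(self) -> list[Tensor]:
        return [self.seg_logits] + list(self.side_logits)


class AuxHead(nn.Module):
    """Table-style auxiliary unit: adapter 1×1 conv → two conv/pool stages →
    flatten → linear(D)."""

    def __init__(self, spec: AuxHeadSpec, seed: int, path: str):
        h, w = spec.spatial
        if h < 4 or w < 4:
            raise ModelConfigError(
                f"aux head needs spatial size >= 4, got {spec.spatial}")
        self.spec = spec
        self.adapter = nn.Conv2d(spec.in_channels, 3, 1, 0, seed, f"{path}.adapter")
        self.conv1 = nn.Conv2d(3, 3, 3, 1, seed, f"{path}.conv1")
        self.conv2 = nn.Conv2d(3, 3, 3, 1, seed, f"{path}.conv2")
        self.fc = nn.Linear(spec.flatten_size, spec.out_dim, seed, f"{path}.fc")

    def __call__(self, features: Tensor) -> Tensor:
        x = self.adapter(features)
        x = nn.maxpool2d(nn.relu(self.conv1(x)), ceil_mode=True)
        x = nn.maxpool2d(nn.relu(self.conv2(x)), ceil_mode=True)
        ph, pw = self.spec.pooled
        x = nn.resize_nearest(x, ph, pw)  # identity at the reference size
        return self.fc(nn.flatten(x))


def aux_head_forward(features: np.ndarray | Tensor, head: AuxHead) -> np.ndarray:
    """Run one auxiliary head on a single (C, s, s') feature map."""
    data = features.data if isinstance(features, Tensor) else np.asarray(features)
    if data.ndim == 3:
        data = data[None]
    out = head(Tensor(data.transpose(0, 2, 3, 1)))  # NCHW -> internal NHWC
    return out.data[0]


class _DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, seed, path):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, 1, seed, f"{path}.c1")
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, 1, seed, f"{path}.c2")

    def __call__(self, x):
        return nn.relu(self.c2(nn.relu(self.c1(x))))


class UNet(nn.Module):
    """Plain UNet: n_stages resolution levels (incl. bottleneck), nearest
    upsampling + conv in the decoder, skip concatenation."""

    def __init__(self, spec: MultiTaskModelSpec):
        s = spec.resolved_stages
        base = max(2, round(64 * spec.width_scale))
        chans = [base * 2 ** i for i in range(s)]
        seed = spec.seed
        self.spec = spec
        self.downsample_factor = 2 ** (s - 1)
        self.enc = [_DoubleConv(3 if i == 0 else chans[i - 1], chans[i],
                                seed, f"unet.enc{i}") for i in range(s - 1)]
        self.bottleneck = _DoubleConv(chans[s - 2], chans[s - 1],
                                      seed, "unet.bottleneck")
        self.up_convs = [nn.Conv2d(chans[i + 1], chans[i], 3, 1, seed,
                                   f"unet.up{i}") for i in range(s - 2, -1, -1)]
        self.dec = [_DoubleConv(2 * chans[i], chans[i], seed,
                                f"unet.dec{i}") for i in range(s - 2, -1, -1)]
        self.out_conv = nn.Conv2d(chans[0], spec.n_classes, 1, 0, seed, "unet.out")
        self.bottleneck_channels = chans[s - 1]

    def forward_features(self, x: Tensor):
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2d(x)
        bottom = self.bottleneck(x)
        x = bottom
        for up, dec, skip in zip(self.up_convs, self.dec, reversed(skips)):
            x = nn.relu(up(nn.upsample2x(x)))
            x = dec(nn.concat_channels([skip, x]))
        return nn.to_nchw(self.out_conv(x)), bottom


class _RSU(nn.Module):
    """Residual U-block: a 2-level mini-UNet whose output is added to the
    input projection — the nesting that gives U2Net its name."""

    def __init__(self, in_ch, mid_ch, out_ch, seed, path):
        self.cin = nn.Conv2d(in_ch, out_ch, 3, 1, seed, f"{path}.cin")
        self.e1 = nn.Conv2d(out_ch, mid_ch, 3, 1, seed, f"{path}.e1")
        self.e2 = nn.Conv2d(mid_ch, mid_ch, 3, 1, seed, f"{path}.e2")
        self.bottom = nn.Conv2d(mid_ch, mid_ch, 3, 1, seed, f"{path}.bottom")
        self.d2 = nn.Conv2d(2 * mid_ch, mid_ch, 3, 1, seed, f"{path}.d2")
        self.d1 = nn.Conv2d(2 * mid_ch, out_ch, 3, 1, seed, f"{path}.d1")

    def __call__(self, x):
        hx = nn.relu(self.cin(x))
        e1 = nn.relu(self.e1(hx))
        e2 = nn.relu(self.e2(nn.maxpool2d(e1)))
        bottom = nn.relu(self.bottom(e2))
        d2 = nn.relu(self.d2(nn.concat_channels([bottom, e2])))
        d1 = nn.relu(self.d1(nn.concat_channels([nn.upsample2x(d2), e1])))
        return nn.add(d1, hx)


class U2Net(nn.Module):
    """Nested-U backbone with deep-supervision side outputs.

    ``n_stages`` counts the encoder stages; the decoder has n_stages − 1
    stages, and side outputs come from the bottom stage plus every decoder
    stage (n_stages side maps), fused by a 1×1 convolution.
    """

    def __init__(self, spec: MultiTaskModelSpec):
        s = spec.resolved_stages
        base = max(2, round(16 * spec.width_scale * 4))  # 64 at scale 1
        chans = [min(base * 2 ** i, base * 8) for i in range(s)]
        seed = spec.seed
        self.spec = spec
        # one extra factor of 2: each residual U-block pools once internally
        self.downsample_factor = 2 ** s
        self.enc = [_RSU(3 if i == 0 else chans[i - 1], max(2, chans[i] // 2),
                         chans[i], seed, f"u2net.enc{i}") for i in range(s)]
        self.dec = [_RSU(chans[i] + chans[i + 1], max(2, chans[i] // 2),
                         chans[i], seed, f"u2net.dec{i}")
                    for i in range(s - 2, -1, -1)]
        # side convs: bottom (enc s-1) then decoder stages deepest-first
        side_chans = [chans[s - 1]] + [chans[i] for i in range(s - 2, -1, -1)]
        self.side_convs = [nn.Conv2d(c, spec.n_classes, 3, 1, seed,
                                     f"u2net.side{j}")
                           for j, c in enumerate(side_chans)]
        self.fuse = nn.Conv2d(s * spec.n_classes, spec.n_classes, 1, 0,
                              seed, "u2net.fuse")
        self.stage_channels = side_chans  # bottom + decoder stages

    def forward_features(self, x: Tensor):
        H, W = x.data.shape[1], x.data.shape[2]
        s = self.spec.resolved_stages
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            skips.append(x)
            if i < s - 1:
                x = nn.maxpool2d(x)
        bottom = skips[-1]
        stage_feats = [bottom]
        x = bottom
        for dec, skip in zip(self.dec, reversed(skips[:-1])):
            x = dec(nn.concat_channels([nn.upsample2x(x), skip]))
            stage_feats.append(x)
        sides = [nn.resize_nearest(conv(f), H, W)
                 for conv, f in zip(self.side_convs, stage_feats)]
        fused = self.fuse(nn.concat_channels(sides))
        return (nn.to_nchw(fused), [nn.to_nchw(s) for s in sides],
                stage_feats)


class MultiTaskModel(nn.Module):
    """A backbone plus its attached auxiliary HOG-regression heads."""

    def __init__(self, spec: MultiTaskModelSpec):
        self.spec = spec
        placement = spec.resolved_placement
        W, H = spec.input_size
        if spec.backbone == "unet":
            self.backbone = UNet(spec)
        else:
            self.backbone = U2Net(spec)
        f = self.backbone.downsample_factor
        if W % f or H % f:
            raise ModelConfigError(
                f"input size {spec.input_size} not divisible by the backbone's "
                f"downsampling factor {f}")
        self.heads: list[AuxHead] = []
        if placement == "none":
            pass
        elif spec.backbone == "unet" or placement == "bottleneck_only":
            bh, bw = H // f, W // f
            ch = (self.backbone.bottleneck_channels if spec.backbone == "unet"
                  else self.backbone.stage_channels[0])
            self.heads = [AuxHead(AuxHeadSpec(ch, (bh, bw), spec.hog_dim),
                                  spec.seed, "head0")]
        else:  # u2net, all_decoder_stages: bottom + each decoder stage
            s = spec.resolved_stages
            self.heads = []
            for j, ch in enumerate(self.backbone.stage_channels):
                factor = 2 ** (s - 1 - j)
                self.heads.append(
                    AuxHead(AuxHeadSpec(ch, (H // factor, W // factor),
                                        spec.hog_dim), spec.seed, f"head{j}"))

    def __call__(self, x: np.ndarray | Tensor, with_heads: bool = True
                 ) -> MultiTaskOutput:
        """Forward pass. ``x`` is an NCHW (or CHW) image batch in [0, 1]."""
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        if data.ndim == 3:
            data = data[None]
        x = Tensor(data.transpose(0, 2, 3, 1))  # internal layout is NHWC
        if self.spec.backbone == "unet":
            logits, bottom = self.backbone.forward_features(x)
            feats = [bottom]
            sides = []
        else:
            logits, sides, feats = self.backbone.forward_features(x)
        preds = [h(f) for h, f in zip(self.heads, feats)] if with_heads else []
        return MultiTaskOutput(seg_logits=logits, hog_preds=preds,
                               side_logits=sides)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """Argmax segmentation of one (H, W, 3) image in [0, 1]."""
        x = np.transpose(np.asarray(image, dtype=np.float64), (2, 0, 1))[None]
        out = self(x, with_heads=False)
        return out.seg_logits.data[0].argmax(axis=0).astype(np.int64)


def build_model(spec: MultiTaskModelSpec) -> MultiTaskModel:
    """Construct the multi-task model described by ``spec``."""
    return MultiTaskModel(spec)


def count_heads(model: MultiTaskModel) -> int:
    """Number of auxiliary regression units attached to the model."""
    return len(model.heads)
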