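"""The trainable localization + segmentation network.

A simplified encoder-decoder backbone produces a full-resolution feature map
(output stride 1): the encoder halves resolution and doubles channels at each
level with residual-style 3x3 conv blocks, the decoder restores resolution
with bilinear x2 upsampling plus a single conv block, and additive shortcuts
connect each encoder level to its decoder counterpart.

Four heads read the feature map: a 2-channel sigmoid classification head
(inner/outer center heatmaps), two disjoint radius-regression branches, a
shared 2-channel sub-pixel offset head, and a mask head applied to a square
RoI cropped around the outer-circle center. The mask head downsamples by 8
with three stride-2 conv blocks; its probabilities are bilinearly resized
back to the RoI size for assembly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .nn import Tensor

__all__ = ["NetConfig", "PredictionMaps", "IrisNet", "crop_roi",
           "save_checkpoint", "load_checkpoint"]

logger = logging.getLogger(__name__)

MULTIPLE = 32  # input spatial sizes must be divisible by this
MIN_ROI = 8


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``depth`` counts encoder levels (the full-scale default is 5);
    ``crop_scale`` sets the RoI side as a multiple of the predicted outer
    radius (2.0 covers the full iris; 1.0 is the literal radius-sized crop).
    ``tiny`` marks the reduced desk-scale preset.
    """

    depth: int = 5
    base_channels: int = 16
    feature_channels: int = 32
    head_hidden: int = 32
    bottleneck_blocks: int = 2
    crop_scale: float = 2.0
    radius_bias_init: float = 12.0
    tiny: bool = False

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.crop_scale <= 0:
            raise ValueError("crop_scale must be positive")

    @staticmethod
    def tiny_preset(**overrides) -> "NetConfig":
        """Reduced configuration that trains in minutes on one CPU."""
        cfg = NetConfig(depth=3, base_channels=8, feature_channels=32,
                        head_hidden=8, bottleneck_blocks=3, tiny=True)
        return replace(cfg, **overrides) if overrides else cfg

    def to_dict(self) -> dict:
        return {"depth": self.depth, "base_channels": self.base_channels,
                "feature_channels": self.feature_channels,
                "head_hidden": self.head_hidden,
                "bottleneck_blocks": self.bottleneck_blocks,
                "crop_scale": self.crop_scale,
                "radius_bias_init": self.radius_bias_init, "tiny": self.tiny}


@dataclass
class PredictionMaps:
    """Decoded-to-numpy network outputs for a single image (channel-last)."""

    heat: np.ndarray     # (H, W, 2) in (0, 1)
    radius: np.ndarray   # (H, W, 2) px
    offset: np.ndarray   # (H, W, 2) (dx, dy)
    feature: np.ndarray  # (H, W, F)


class _EncoderLevel(nn.Layer):
    """Stride-2 downsampling conv block plus one residual conv block."""

    def __init__(self, in_ch: int, out_ch: int, rng) -> None:
        super().__init__()
        self.down = nn.ConvBlock(in_ch, out_ch, stride=2, rng=rng)
        self.block = nn.ConvBlock(out_ch, out_ch, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.down(x)
        return self.block(x) + x


class _DecoderLevel(nn.Layer):
    """Bilinear x2 upsampling followed by a single conv block."""

    def __init__(self, in_ch: int, out_ch: int, rng) -> None:
        super().__init__()
        self.block = nn.ConvBlock(in_ch, out_ch, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block(nn.upsample2x(x))


class _Head(nn.Layer):
    """Two 3x3 conv+relu layers then a 1x1 projection (three conv layers)."""

    def __init__(self, in_ch: int, hidden: int, out_ch: int, rng,
                 bias_init: float = 0.0) -> None:
        super().__init__()
        self.hidden = hidden
        self.c1 = nn.Conv2d(in_ch, hidden, rng=rng)
        self.c2 = nn.Conv2d(hidden, hidden, rng=rng)
        self.proj = nn.Conv2d(hidden, out_ch, kernel=1, rng=rng, bias_init=bias_init)

    def tail(self, h1: Tensor) -> Tensor:
        """Layers after the first conv+relu (for the fused multi-head path)."""
        return self.proj(nn.relu(self.c2(h1)))

    def __call__(self, x: Tensor) -> Tensor:
        return self.tail(nn.relu(self.c1(x)))


class _MaskHead(nn.Layer):
    """Three stride-2 3x3 conv blocks, a 1x1 projection, and a sigmoid."""

    def __init__(self, in_ch: int, hidden: int, rng) -> None:
        super().__init__()
        self.b1 = nn.ConvBlock(in_ch, hidden, stride=2, rng=rng)
        self.b2 = nn.ConvBlock(hidden, hidden, stride=2, rng=rng)
        self.b3 = nn.ConvBlock(hidden, hidden, stride=2, rng=rng)
        self.proj = nn.Conv2d(hidden, 1, kernel=1, rng=rng)

    def __call__(self, roi: Tensor) -> Tensor:
        return nn.sigmoid(self.proj(self.b3(self.b2(self.b1(roi)))))


class IrisNet(nn.Layer):
    """Backbone plus heads; see the module docstring for the layout."""

    def __init__(self, config: NetConfig = NetConfig(), seed: int = 0) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.base_channels
        self.stem = nn.ConvBlock(3, ch, rng=rng)
        enc_channels = [ch * 2**i for i in range(config.depth)]
        self.encoder = [
            _EncoderLevel(enc_channels[i], enc_channels[i + 1], rng)
            for i in range(config.depth - 1)
        ]
        # extra residual blocks at the deepest level: the circle center sits
        # in the featureless pupil, so the radius/heat evidence lies a full
        # radius away and the receptive field must span the outer circle
        deep = enc_channels[-1]
        self.bottleneck = [nn.ConvBlock(deep, deep, rng=rng)
                           for _ in range(config.bottleneck_blocks)]
        self.decoder = [
            _DecoderLevel(enc_channels[i + 1], enc_channels[i], rng)
            for i in reversed(range(config.depth - 1))
        ]
        self.feature_conv = nn.ConvBlock(ch, config.feature_channels, rng=rng)
        fc, hh = config.feature_channels, config.head_hidden
        # heatmap bias starts low so the sigmoid output is mostly background;
        # radius outputs start at a mid-scale radius prior: an output bias
        # moves only ~lr per optimizer step, so starting at zero would leave
        # a systematic transient that short schedules cannot amortize
        self.heat_head = _Head(fc, hh, 2, rng, bias_init=-2.19)
        self.radius_head_inner = _Head(fc, hh, 1, rng,
                                       bias_init=config.radius_bias_init)
        self.radius_head_outer = _Head(fc, hh, 1, rng,
                                       bias_init=config.radius_bias_init)
        self.offset_head = _Head(fc, hh, 2, rng)
        self.mask_head_net = _MaskHead(fc, hh, rng)

    # -- forward pieces ----------------------------------------------------
    def backbone(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) image tensor -> (N, F, H, W) full-resolution feature."""
        h, w = x.shape[2], x.shape[3]
        if h % MULTIPLE or w % MULTIPLE:
            raise ValueError(
                f"input size {h}x{w} must be a multiple of {MULTIPLE}; "
                "apply central cropping/padding first"
            )
        x = self.stem(x)
        skips = [x]
        for level in self.encoder:
            x = level(x)
            skips.append(x)
        for block in self.bottleneck:
            x = block(x) + x
        for i, level in enumerate(self.decoder):
            x = level(x) + skips[-(i + 2)]
        return self.feature_conv(x)

    def _fused_head_weights(self):
        """Weights for evaluating the four heads as three fused convolutions.

        Layer 1 stacks the heads' first convs along the output axis; layers 2
        and 3 are block-diagonal so each head only sees its own hidden
        channels. Parameters remain disjoint per head (the zero blocks are
        constants); only the evaluation is fused, which shares the
        full-resolution patch matrices that dominate the step cost.
        """
        hlist = [self.heat_head, self.radius_head_inner,
                 self.radius_head_outer, self.offset_head]
        total = sum(h.hidden for h in hlist)

        def zeros(shape):
            return Tensor(np.zeros(shape, dtype=np.float32))

        def block_diag(weights, kernel):
            rows, a = [], 0
            for w in weights:
                out_ch, in_ch = w.shape[0], w.shape[1]
                parts = []
                if a:
                    parts.append(zeros((out_ch, a, kernel, kernel)))
                parts.append(w)
                if total - a - in_ch:
                    parts.append(zeros((out_ch, total - a - in_ch, kernel, kernel)))
                rows.append(parts[0] if len(parts) == 1 else nn.concat(parts, axis=1))
                a += in_ch
            return nn.concat(rows, axis=0)

        w1 = nn.concat([h.c1.weight for h in hlist], axis=0)
        b1 = nn.concat([h.c1.bias for h in hlist], axis=0)
        w2 = block_diag([h.c2.weight for h in hlist], 3)
        b2 = nn.concat([h.c2.bias for h in hlist], axis=0)
        w3 = block_diag([h.proj.weight for h in hlist], 1)
        b3 = nn.concat([h.proj.bias for h in hlist], axis=0)
        return (w1, b1), (w2, b2), (w3, b3)

    def heads(self, feature: Tensor) -> dict[str, Tensor]:
        """All dense heads on a feature map; outputs are (N, C, H, W)."""
        (w1, b1), (w2, b2), (w3, b3) = self._fused_head_weights()
        h1 = nn.relu(nn.conv2d(feature, w1, b1, stride=1, padding=1))
        h2 = nn.relu(nn.conv2d(h1, w2, b2, stride=1, padding=1))
        out = nn.conv2d(h2, w3, b3, stride=1, padding=0)
        # output channel layout: heat(2), radius inner(1), outer(1), offset(2)
        heat = nn.sigmoid(nn.slice_channels(out, 0, 2))
        radius = nn.slice_channels(out, 2, 4)
        offset = nn.slice_channels(out, 4, 6)
        return {"heat": heat, "radius": radius, "offset": offset}

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        feature = self.backbone(x)
        out = self.heads(feature)
        out["feature"] = feature
        return out

    def mask_head(self, roi: Tensor) -> Tensor:
        """RoI feature patch -> native-resolution (side/8) mask probabilities."""
        return self.mask_head_net(roi)

    # -- numpy inference ----------------------------------------------------
    def predict_maps(self, image: np.ndarray) -> PredictionMaps:
        """Run one (H, W, 3) uint8 image through the dense part of the net."""
        x = Tensor(image_to_input(image)[None])
        out = self.forward(x)
        to_hwc = lambda t: np.ascontiguousarray(t.data[0].transpose(1, 2, 0))
        return PredictionMaps(
            heat=to_hwc(out["heat"]),
            radius=to_hwc(out["radius"]),
            offset=to_hwc(out["offset"]),
            feature=to_hwc(out["feature"]),
        )

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def image_to_input(image: np.ndarray) -> np.ndarray:
    """uint8 (H, W, 3) -> float32 (3, H, W) in [-0.5, 0.5]."""
    return (image.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)


def roi_rect(center: tuple[float, float], r: float, crop_scale: float,
             min_side: int = MIN_ROI) -> tuple[int, int, int]:
    """Placement rectangle (y0, x0, side) of the square RoI around a center."""
    if not r > 0:
        raise ValueError("RoI radius must be positive")
    side = int(round(crop_scale * r))
    if side < min_side:
        logger.warning("RoI side %d below minimum, clamping to %d", side, min_side)
        side = min_side
    cx, cy = int(round(center[0])), int(round(center[1]))
    return cy - side // 2, cx - side // 2, side


def crop_roi(feature: Tensor, center: tuple[float, float], r: float,
             crop_scale: float = 2.0) -> tuple[Tensor, tuple[int, int, int]]:
    """Crop a zero-padded square patch of the (N, C, H, W) feature map.

    Returns the patch and its placement rectangle ``(y0, x0, side)`` in image
    coordinates, used later to paste the mask back into the full frame.
    """
    y0, x0, side = roi_rect(center, r, crop_scale)
    return nn.crop2d(feature, y0, x0, side), (y0, x0, side)


def upsample_probs(native: np.ndarray, side: int) -> np.ndarray:
    """Bilinearly resize the mask head's native output back to side x side."""
    return _sk_resize(native.astype(np.float64), (side, side), order=1,
                      mode="edge", anti_aliasing=False)


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(path, net: IrisNet, extra_config: dict | None = None) -> None:
    """Write parameters as an ``.npz`` plus a JSON sidecar of configurations."""
    np.savez(path, **net.state_arrays())
    sidecar = {"net": net.config.to_dict()}
    if extra_config:
        sidecar.update(extra_config)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def load_checkpoint(path) -> tuple[IrisNet, dict]:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    net = IrisNet(NetConfig(**sidecar["net"]))
    with np.load(path) as data:
        net.load_state_arrays(dict(data))
    net.eval()
    return net, sidecar
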