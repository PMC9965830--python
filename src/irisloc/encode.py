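"""Training-target construction: Gaussian center heatmaps, radius/offset maps.

The two iris boundaries are encoded as center-point Gaussians splatted at the
floored circle centers, one heatmap channel per category (0 = inner/pupil,
1 = outer/limbic). Both Gaussians are truncated to the inner-circle disk so
that the loss concentrates on the region where both centers must lie.

With the concentric-region strategy enabled (``use_cgr``), the two channels
share a clipped common value over the region where both Gaussians are
positive, and each channel's own center pixel and its four axis-neighbors are
hard-set to 1.0 and 0.8 — high-activation anchor points that survive the
clipping. These target maps exist only at training time; inference reads the
predicted maps directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Circle, disk_mask

__all__ = [
    "EncodeConfig",
    "TargetMaps",
    "gaussian_sigma",
    "render_gaussian",
    "build_heatmaps",
    "build_regression_targets",
    "encode_sample",
]


@dataclass(frozen=True)
class EncodeConfig:
    """Heatmap-encoding hyperparameters.

    ``alpha_inner``/``alpha_outer`` weight the two Gaussians inside the shared
    concentric region; ``min_overlap`` sets the adaptive Gaussian radius (the
    minimum IoU a box displaced by the placement radius must keep);
    ``neighbor_value`` and ``clip_max`` are the hard-coded activation levels.
    """

    use_cgr: bool = True
    alpha_inner: float = 1.0
    alpha_outer: float = 1.0
    min_overlap: float = 0.7
    neighbor_value: float = 0.8
    clip_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_max < self.neighbor_value < 1.0):
            raise ValueError("need 0 < clip_max < neighbor_value < 1")
        if not (0.0 < self.min_overlap < 1.0):
            raise ValueError("min_overlap must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "use_cgr": self.use_cgr,
            "alpha_inner": self.alpha_inner,
            "alpha_outer": self.alpha_outer,
            "min_overlap": self.min_overlap,
            "neighbor_value": self.neighbor_value,
            "clip_max": self.clip_max,
        }


@dataclass
class TargetMaps:
    """Ground-truth maps for one image.

    heat : (H, W, 2) float32 in [0, 1]
    radius : (H, W, 2) float32, radius in px on the positive-sample support
    offset : (H, W, 2) float32, sub-pixel (dx, dy) at the center pixels only
    pos_mask : (H, W, 2) uint8, support of the radius supervision (heat > 0)
    center_mask : (H, W, 2) uint8, exactly one pixel per channel
    """

    heat: np.ndarray
    radius: np.ndarray
    offset: np.ndarray
    pos_mask: np.ndarray
    center_mask: np.ndarray


def gaussian_sigma(object_radius_px: float, min_overlap: float = 0.7,
                   min_sigma: float = 0.0) -> float:
    """Adaptive Gaussian width for a circle of radius ``r``.

    The circle's circumscribing square (side ``2r``) is treated as the object
    box; ``g`` is the largest placement radius such that a corner displaced by
    ``g`` still yields box IoU >= ``min_overlap`` in the worst of the three
    displacement cases (both corners out, both in, box shifted), taking the
    smallest positive quadratic root in each case. Returns ``sigma = g / 3``.
    An optional ``min_sigma`` floor is available for experiments with very
    small circles, whose adaptive width falls below one pixel.
    """
    if not object_radius_px > 0:
        raise ValueError(f"object radius must be > 0, got {object_radius_px}")
    if not (0.0 < min_overlap < 1.0):
        raise ValueError(f"min_overlap must be in (0, 1), got {min_overlap}")
    h = w = 2.0 * object_radius_px
    o = min_overlap

    # box shifted diagonally: inter=(w-g)(h-g), union=2wh-inter
    a1, b1, c1 = 1.0, h + w, w * h * (1 - o) / (1 + o)
    g1 = (b1 - math.sqrt(b1 * b1 - 4 * a1 * c1)) / (2 * a1)

    # both corners shrink inward: inter=(w-2g)(h-2g), union=wh
    a2, b2, c2 = 4.0, 2 * (h + w), (1 - o) * w * h
    g2 = (b2 - math.sqrt(b2 * b2 - 4 * a2 * c2)) / (2 * a2)

    # both corners grow outward: inter=wh, union=(w+2g)(h+2g)
    a3, b3, c3 = 4.0 * o, -2.0 * o * (h + w), (o - 1) * w * h
    g3 = (-b3 + math.sqrt(b3 * b3 - 4 * a3 * c3)) / (2 * a3)

    g = min(g1, g2, g3)
    return max(g / 3.0, min_sigma, 1e-3)


def render_gaussian(
    center: tuple[float, float],
    sigma: float,
    support: Circle | None,
    shape: tuple[int, int],
) -> np.ndarray:
    """Splat one unnormalized Gaussian peaked at the floored center.

    Values are ``exp(-((j-px̄)² + (i-pȳ)²) / (2σ²))`` inside ``support`` (a
    disk; everywhere when None), 0 outside; the peak pixel is exactly 1.
    """
    h, w = shape
    px, py = center
    cx, cy = int(math.floor(px)), int(math.floor(py))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"center ({px}, {py}) falls outside image of shape {shape}")
    ys, xs = np.ogrid[:h, :w]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    heat = np.exp(-d2 / (2.0 * sigma * sigma)).astype(np.float32)
    heat[cy, cx] = 1.0
    if support is not None:
        heat = np.where(disk_mask(support, shape), heat, np.float32(0.0))
    return heat


def _axis_neighbors(cx: int, cy: int, shape: tuple[int, int]):
    h, w = shape
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nx, ny = cx + dx, cy + dy
        if 0 <= nx < w and 0 <= ny < h:
            yield ny, nx


def build_heatmaps(
    inner: Circle,
    outer: Circle,
    shape: tuple[int, int],
    cfg: EncodeConfig = EncodeConfig(),
) -> np.ndarray:
    """Build the (H, W, 2) ground-truth heatmap for one annotated pair.

    Both channels are truncated to the inner-circle disk. Without the
    concentric strategy each channel is simply its truncated Gaussian. With it
    enabled, pixels where both Gaussians are positive receive the shared value
    ``min(clip_max, (α_in·Y_in + α_out·Y_out) / 2)`` in both channels (1.0
    where both Gaussians are exactly 1, 0 where either vanishes), then each
    channel's own center pixel is forced to 1.0 and its four axis-neighbors
    to ``neighbor_value``.
    """
    if not inner.r < outer.r:
        raise ValueError("inner radius must be smaller than outer radius")
    channels = []
    centers = []
    for circ in (inner, outer):
        sigma = gaussian_sigma(circ.r, cfg.min_overlap)
        channels.append(render_gaussian((circ.x, circ.y), sigma, inner, shape))
        centers.append((int(math.floor(circ.x)), int(math.floor(circ.y))))
    heat = np.stack(channels, axis=-1)

    if cfg.use_cgr:
        y_in, y_out = heat[..., 0], heat[..., 1]
        both_pos = (y_in > 0) & (y_out > 0)
        both_one = (y_in == 1.0) & (y_out == 1.0)
        shared = np.minimum(
            np.float32(cfg.clip_max),
            0.5 * (cfg.alpha_inner * y_in + cfg.alpha_outer * y_out),
        )
        shared = np.where(both_one, np.float32(1.0), shared)
        for k in range(2):
            heat[..., k] = np.where(both_pos, shared, heat[..., k])
        for k, (cx, cy) in enumerate(centers):
            heat[cy, cx, k] = 1.0
            for ny, nx in _axis_neighbors(cx, cy, shape):
                heat[ny, nx, k] = cfg.neighbor_value
    else:
        for k, (cx, cy) in enumerate(centers):
            heat[cy, cx, k] = 1.0
    return heat.astype(np.float32)


def build_regression_targets(
    inner: Circle,
    outer: Circle,
    heat: np.ndarray,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Radius/offset targets and their supervision supports.

    Every pixel with positive heat is responsible for the radius of its
    category; the sub-pixel offset is supervised only at the floored center.
    """
    h, w = shape
    radius = np.zeros((h, w, 2), dtype=np.float32)
    offset = np.zeros((h, w, 2), dtype=np.float32)
    pos_mask = (heat > 0).astype(np.uint8)
    center_mask = np.zeros((h, w, 2), dtype=np.uint8)
    centers = []
    for k, circ in enumerate((inner, outer)):
        radius[..., k] = np.where(pos_mask[..., k] > 0, np.float32(circ.r), 0.0)
        cx, cy = int(math.floor(circ.x)), int(math.floor(circ.y))
        center_mask[cy, cx, k] = 1
        centers.append((cx, cy))
        # offset channels are (dx, dy), shared across the two categories
        offset[cy, cx, 0] = circ.x - cx
        offset[cy, cx, 1] = circ.y - cy
    if centers[0] == centers[1]:
        # both centers fall in one pixel: a single shared offset must serve
        # both circles, and the mean fractional part bounds the per-circle
        # decoding error below half a pixel
        cx, cy = centers[0]
        offset[cy, cx, 0] = 0.5 * ((inner.x - cx) + (outer.x - cx))
        offset[cy, cx, 1] = 0.5 * ((inner.y - cy) + (outer.y - cy))
    return radius, offset, pos_mask, center_mask


def encode_sample(
    inner: Circle,
    outer: Circle,
    shape: tuple[int, int],
    cfg: EncodeConfig = EncodeConfig(),
) -> TargetMaps:
    """Full target encoding for one annotation pair."""
    heat = build_heatmaps(inner, outer, shape, cfg)
    radius, offset, pos_mask, center_mask = build_regression_targets(
        inner, outer, heat, shape
    )
    return TargetMaps(heat=heat, radius=radius, offset=offset,
                      pos_mask=pos_mask, center_mask=center_mask)
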