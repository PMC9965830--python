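"""Post-processing-free decoding of network outputs.

Each heatmap channel's global maximum is the detected center; the sub-pixel
offset and radius are read at that pixel and combined directly into a circle
(no mask fitting, Hough transform, or integro-differential search anywhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Circle, INNER, OUTER
from .net import PredictionMaps

__all__ = ["LocalizationResult", "peak_pick", "decode_circles", "assemble_mask"]

logger = logging.getLogger(__name__)


@dataclass
class LocalizationResult:
    """Decoded circles with their peak confidences and the assembled mask."""

    inner: Circle
    outer: Circle
    score_inner: float
    score_outer: float
    mask: np.ndarray  # (H, W) uint8 in {0, 1}

    def to_dict(self) -> dict:
        return {
            "inner": {"x": self.inner.x, "y": self.inner.y, "r": self.inner.r,
                      "score": self.score_inner},
            "outer": {"x": self.outer.x, "y": self.outer.y, "r": self.outer.r,
                      "score": self.score_outer},
        }


def peak_pick(heat_channel: np.ndarray) -> tuple[int, int, float]:
    """Global argmax of one heatmap channel.

    Returns ``(x, y, score)``; ties are broken toward the smallest row-major
    index (numpy argmax convention).
    """
    heat = np.asarray(heat_channel)
    if heat.size == 0:
        raise ValueError("empty heatmap")
    flat_idx = int(heat.argmax())
    y, x = np.unravel_index(flat_idx, heat.shape)
    return int(x), int(y), float(heat[y, x])


def decode_circles(pred: PredictionMaps, s: float = 1.0) -> tuple[Circle, Circle, tuple[float, float]]:
    """Convert prediction maps to the two circles.

    Per category: ``x̂ = x_peak * s + dx``, ``ŷ = y_peak * s + dy`` with the
    offset read at the peak pixel, and the radius read there too (clamped to
    >= 1 px so an untrained net still yields a usable RoI).
    """
    circles = []
    scores = []
    for k, category in enumerate((INNER, OUTER)):
        x, y, score = peak_pick(pred.heat[..., k])
        dx, dy = float(pred.offset[y, x, 0]), float(pred.offset[y, x, 1])
        r = max(float(pred.radius[y, x, k]), 1.0)
        circles.append(Circle(x * s + dx, y * s + dy, r, category))
        scores.append(score)
    return circles[0], circles[1], (scores[0], scores[1])


def assemble_mask(
    roi_probs: np.ndarray,
    placement_rect: tuple[int, int, int],
    image_shape: tuple[int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Paste RoI probabilities into a zero canvas and binarize (ties positive)."""
    h, w = image_shape
    y0, x0, side = placement_rect
    probs = np.asarray(roi_probs)
    if probs.shape != (side, side):
        raise ValueError(f"RoI probabilities {probs.shape} do not match side {side}")
    mask = np.zeros((h, w), dtype=np.uint8)
    ys, ye = max(y0, 0), min(y0 + side, h)
    xs, xe = max(x0, 0), min(x0 + side, w)
    if ys >= ye or xs >= xe:
        logger.warning("RoI rectangle %s lies outside the image; empty mask",
                       placement_rect)
        return mask
    window = probs[ys - y0:ye - y0, xs - x0:xe - x0]
    mask[ys:ye, xs:xe] = (window >= threshold).astype(np.uint8)
    return mask
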