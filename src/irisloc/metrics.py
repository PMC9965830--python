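"""Evaluation protocols: circle box IoU, circle-area IoU, normalized
Hausdorff distance on boundary points, mask error rate E1, mask IoU, and E1
on rubber-sheet-normalized masks."""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .core import BBox, Circle, circle_bbox
from .normalize import rubber_sheet

__all__ = [
    "EvalReport",
    "box_iou",
    "circle_area_iou",
    "norm_hausdorff",
    "e1",
    "mask_iou",
    "e1_norm",
]


@dataclass
class EvalReport:
    """Dataset-level means of the per-image metrics."""

    miou_box_inner: float
    miou_box_outer: float
    miou_box_avg: float
    mhdist_inner: float
    mhdist_outer: float
    e1_mask: float
    miou_mask: float
    e1_norm: float
    n_images: int

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def summary(self) -> str:
        lines = ["metric             value", "-" * 26]
        for f in fields(self):
            val = getattr(self, f.name)
            fmt = f"{val:d}" if f.name == "n_images" else f"{val:.4f}"
            lines.append(f"{f.name:<18s} {fmt}")
        return "\n".join(lines)


def _box_intersection(a: BBox, b: BBox) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    return max(w, 0.0) * max(h, 0.0)


def box_iou(a: Circle, b: Circle) -> float:
    """IoU of the squares circumscribing the two circles."""
    ba, bb = circle_bbox(a), circle_bbox(b)
    inter = _box_intersection(ba, bb)
    union = ba.area + bb.area - inter
    return inter / union


def circle_area_iou(a: Circle, b: Circle) -> float:
    """Exact IoU of the two disks (lens area via circular segments)."""
    d = math.hypot(a.x - b.x, a.y - b.y)
    r1, r2 = a.r, b.r
    area1, area2 = math.pi * r1 * r1, math.pi * r2 * r2
    if d >= r1 + r2:
        inter = 0.0
    elif d <= abs(r1 - r2):
        inter = min(area1, area2)
    else:
        # lens: sum of the two circular segments cut by the radical line
        c1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
        c2 = d - c1
        seg1 = r1 * r1 * math.acos(max(-1.0, min(1.0, c1 / r1))) - c1 * math.sqrt(
            max(r1 * r1 - c1 * c1, 0.0))
        seg2 = r2 * r2 * math.acos(max(-1.0, min(1.0, c2 / r2))) - c2 * math.sqrt(
            max(r2 * r2 - c2 * c2, 0.0))
        inter = seg1 + seg2
    union = area1 + area2 - inter
    return inter / union


def _boundary_points(c: Circle, image_shape: tuple[int, int], n_points: int) -> np.ndarray:
    h, w = image_shape
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = np.stack([(c.x + c.r * np.cos(theta)) / w,
                    (c.y + c.r * np.sin(theta)) / h], axis=1)
    return pts


def norm_hausdorff(a: Circle, b: Circle, image_shape: tuple[int, int],
                   n_points: int = 360) -> float:
    """Symmetric Hausdorff distance between the two circle boundaries,
    sampled at uniform angles with coordinates normalized to [0, 1] (x by the
    image width, y by the height)."""
    pa = _boundary_points(a, image_shape, n_points)
    pb = _boundary_points(b, image_shape, n_points)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def e1(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Pixel disagreement rate: mean XOR of the two binary masks."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return float(np.logical_xor(pred, gt).mean())


def mask_iou(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """IoU of two binary masks; 1.0 when both are empty."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, gt).sum() / union)


def e1_norm(
    pred_mask: np.ndarray,
    pred_circles: tuple[Circle, Circle],
    gt_mask: np.ndarray,
    gt_circles: tuple[Circle, Circle],
    R: int = 64,
    A: int = 360,
) -> float:
    """E1 on rubber-sheet-normalized masks.

    Each mask is unwrapped with its OWN circle pair (prediction with the
    predicted circles, ground truth with the annotated ones), binarized at
    0.5, and compared on the fixed R x A polar grid. Degenerate circle pairs
    score the worst case, 1.0.
    """
    try:
        pred_grid = rubber_sheet(np.asarray(pred_mask, dtype=float),
                                 pred_circles[0], pred_circles[1], R, A).data
        gt_grid = rubber_sheet(np.asarray(gt_mask, dtype=float),
                               gt_circles[0], gt_circles[1], R, A).data
    except ValueError:
        return 1.0
    return e1(pred_grid >= 0.5, gt_grid >= 0.5)
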