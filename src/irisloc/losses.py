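"""Training objectives.

All losses accept either plain numpy arrays (returning a scalar ``Tensor``
whose ``.item()`` is the value) or autodiff tensors from the network, in
which case gradients flow to the predictions. Ground-truth maps and masks
are always treated as constants.

The heatmap objective is the penalty-reduced pixelwise focal loss used by
center-point detectors: positive pixels (target exactly 1) are scored with a
``(1 - p)^2 log p`` term, negatives with ``(1 - y)^4 p^2 log(1 - p)`` so that
pixels near a Gaussian peak are penalized less, and the sum is normalized by
the number of positive pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, absolute, clamp, log, sum_

__all__ = [
    "LossWeights",
    "focal_loss",
    "size_loss",
    "offset_loss",
    "reg_loss",
    "mask_loss",
    "total_loss",
]

logger = logging.getLogger(__name__)

_EPS = 1e-6
_FOCAL_A = 2.0  # positive-term exponent
_FOCAL_B = 4.0  # negative penalty-reduction exponent


@dataclass(frozen=True)
class LossWeights:
    """Combination weights: total = w_loc*cls + w_reg*(λ_size*size + λ_off*off) + w_mask*mask."""

    w_loc: float = 1.0
    w_reg: float = 1.0
    w_mask: float = 1.0
    lambda_size: float = 1.0
    lambda_off: float = 0.1

    def __post_init__(self) -> None:
        if min(self.w_loc, self.w_reg, self.w_mask,
               self.lambda_size, self.lambda_off) < 0:
            raise ValueError("loss weights must be non-negative")

    def to_dict(self) -> dict:
        return {"w_loc": self.w_loc, "w_reg": self.w_reg, "w_mask": self.w_mask,
                "lambda_size": self.lambda_size, "lambda_off": self.lambda_off}


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def focal_loss(pred_heat, gt_heat) -> Tensor:
    """Penalty-reduced focal loss over all heatmap pixels and channels.

    Normalized by the number of target-1 pixels (at least 1); predictions are
    clamped to ``[1e-6, 1 - 1e-6]`` before the logarithms.
    """
    pred = _as_tensor(pred_heat)
    gt = np.asarray(gt_heat, dtype=pred.dtype)
    pos = (gt == 1.0)
    n_pos = max(int(pos.sum()), 1)
    p = clamp(pred, _EPS, 1.0 - _EPS)
    pos_term = (1.0 - p) ** _FOCAL_A * log(p) * pos.astype(pred.dtype)
    neg_term = (
        (p ** _FOCAL_A) * log(1.0 - p)
        * ((1.0 - gt) ** _FOCAL_B * (~pos)).astype(pred.dtype)
    )
    return -(sum_(pos_term) + sum_(neg_term)) / n_pos


def size_loss(pred_radius, gt_radius, mask, mode: str = "all_pos") -> Tensor:
    """L1 radius loss, combined over categories as ``(1/2) Σ_k term_k``.

    ``mask`` is the per-channel supervision support: the positive-sample mask
    (every pixel in the Gaussian region predicts the radius, ``mode="all_pos"``,
    per-channel mean) or the center-pixel mask (``mode="peaks"``, the literal
    two-peak form, per-channel sum).
    """
    if mode not in ("peaks", "all_pos"):
        raise ValueError(f"unknown size-loss mode {mode!r}")
    pred = _as_tensor(pred_radius)
    gt = np.asarray(gt_radius, dtype=pred.dtype)
    m = np.asarray(mask)
    diff = absolute(pred - gt)
    total: Tensor | float = 0.0
    for k in range(m.shape[-1]):
        # full-shape selector: channel k's support, zero elsewhere
        mk = np.zeros(m.shape, dtype=pred.dtype)
        mk[..., k] = (m[..., k] > 0)
        n_k = mk.sum()
        if n_k == 0:
            logger.warning("size_loss: channel %d has empty support; contributes 0", k)
            continue
        term = sum_(diff * mk)
        total = total + (term if mode == "peaks" else term / n_k)
    return 0.5 * total if isinstance(total, Tensor) else _as_tensor(0.0)


def offset_loss(pred_offset, gt_offset, center_mask) -> Tensor:
    """Mean L1 over the two center pixels and the two (dx, dy) components."""
    pred = _as_tensor(pred_offset)
    gt = np.asarray(gt_offset, dtype=pred.dtype)
    cm = np.asarray(center_mask)
    diff = absolute(pred - gt)
    total: Tensor | float = 0.0
    n_terms = 0
    for k in range(cm.shape[-1]):
        mk = (cm[..., k] > 0).astype(pred.dtype)[..., None]
        total = total + sum_(diff * mk)
        n_terms += 2 * int(mk.sum())
    return total / max(n_terms, 1)


def reg_loss(size, off, w: LossWeights = LossWeights()):
    """Combined regression loss ``λ_size * size + λ_off * off``."""
    return w.lambda_size * size + w.lambda_off * off


def mask_loss(pred_roi_mask, gt_roi_mask) -> Tensor:
    """Mean binary cross-entropy over the RoI pixels."""
    pred = _as_tensor(pred_roi_mask)
    gt = np.asarray(gt_roi_mask, dtype=pred.dtype)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = clamp(pred, _EPS, 1.0 - _EPS)
    ll = gt * log(p) + (1.0 - gt) * log(1.0 - p)
    return -sum_(ll) / gt.size


def total_loss(cls, reg, mask, w: LossWeights = LossWeights()):
    """Weighted total ``w_loc*cls + w_reg*reg + w_mask*mask``."""
    return w.w_loc * cls + w.w_reg * reg + w.w_mask * mask
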