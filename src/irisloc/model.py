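"""Model/Results interface tying the pieces together.

``IrisLocalizationModel`` holds the data and every configuration block;
``fit()`` runs the encode -> forward -> loss -> Adam loop and returns an
``IrisLocalizationResults`` carrying the trained network, the per-epoch loss
history, validation diagnostics, and ``predict`` / ``evaluate`` / ``save``
methods. The organisation mirrors statistical modelling packages: the model
object is cheap to build, all estimation state lives on the results object.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import losses as L
from .core import Circle, EyeSample
from .decode import LocalizationResult, assemble_mask, decode_circles
from .encode import EncodeConfig, encode_sample
from .metrics import EvalReport, box_iou, e1, e1_norm, mask_iou, norm_hausdorff
from .net import (IrisNet, NetConfig, crop_roi, image_to_input, load_checkpoint,
                  roi_rect, save_checkpoint, upsample_probs)
from .nn import Adam, Tensor, permute

__all__ = ["TrainConfig", "IrisLocalizationModel", "IrisLocalizationResults",
           "preprocess", "preprocess_sample"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, plateau-decayed learning rate)."""

    lr: float = 0.001
    weight_decay: float = 0.0004
    batch_size: int = 6
    epochs: int = 120
    lr_factor: float = 0.5
    lr_patience: int = 10
    warmup_steps: int = 100
    grad_clip: float = 5.0
    val_fraction: float = 0.1
    size_mode: str = "all_pos"
    seed: int = 0

    def to_dict(self) -> dict:
        return {"lr": self.lr, "weight_decay": self.weight_decay,
                "batch_size": self.batch_size, "epochs": self.epochs,
                "lr_factor": self.lr_factor, "lr_patience": self.lr_patience,
                "warmup_steps": self.warmup_steps, "grad_clip": self.grad_clip,
                "val_fraction": self.val_fraction, "size_mode": self.size_mode,
                "seed": self.seed}


# ---------------------------------------------------------------------------
# preprocessing: central crop / zero-pad to a multiple-of-32 target size
# ---------------------------------------------------------------------------

def _axis_offset(src: int, dst: int) -> int:
    """Signed placement offset of the source axis inside the target axis."""
    return (dst - src) // 2


def preprocess(image: np.ndarray, target_size: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]]:
    """Centrally crop/pad an image to ``target_size`` (per axis independently).

    Returns the new image and the ``(dx, dy)`` translation that maps source
    coordinates to target coordinates (negative when cropping).
    """
    th, tw = target_size
    if th % 32 or tw % 32:
        raise ValueError(f"target size {target_size} must be multiples of 32")
    h, w = image.shape[:2]
    dy, dx = _axis_offset(h, th), _axis_offset(w, tw)
    out_shape = (th, tw) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    sy, ty = max(0, -dy), max(0, dy)
    sx, tx = max(0, -dx), max(0, dx)
    ch, cw = min(h, th), min(w, tw)
    out[ty:ty + ch, tx:tx + cw] = image[sy:sy + ch, sx:sx + cw]
    return out, (dx, dy)


def preprocess_sample(sample: EyeSample, target_size: tuple[int, int]) -> EyeSample:
    """Crop/pad an annotated sample, translating circles consistently."""
    image, (dx, dy) = preprocess(sample.image, target_size)
    mask, _ = preprocess(sample.mask, target_size)
    return EyeSample(image=image, inner=sample.inner.translated(dx, dy),
                     outer=sample.outer.translated(dx, dy), mask=mask,
                     name=sample.name)


def _nearest_resize(arr: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor square resize (used for RoI ground-truth masks)."""
    n = arr.shape[0]
    idx = np.clip(np.round((np.arange(size) + 0.5) * n / size - 0.5).astype(int), 0, n - 1)
    return arr[np.ix_(idx, idx)]


def _crop_pad_2d(arr: np.ndarray, y0: int, x0: int, side: int) -> np.ndarray:
    out = np.zeros((side, side), dtype=arr.dtype)
    h, w = arr.shape
    ys, ye = max(y0, 0), min(y0 + side, h)
    xs, xe = max(x0, 0), min(x0 + side, w)
    if ys < ye and xs < xe:
        out[ys - y0:ye - y0, xs - x0:xe - x0] = arr[ys:ye, xs:xe]
    return out


def _native_side(side: int) -> int:
    for _ in range(3):
        side = (side + 1) // 2
    return side


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class IrisLocalizationModel:
    """Double-center iris localization/segmentation model over a sample set."""

    def __init__(
        self,
        samples: list[EyeSample],
        net_config: NetConfig = NetConfig(),
        encode_config: EncodeConfig = EncodeConfig(),
        loss_weights: L.LossWeights = L.LossWeights(),
        train_config: TrainConfig = TrainConfig(),
    ) -> None:
        if not samples:
            raise ValueError("no training samples provided")
        shapes = {s.shape for s in samples}
        if len(shapes) != 1:
            raise ValueError(f"samples have mixed shapes {shapes}; preprocess first")
        self.samples = list(samples)
        self.shape = samples[0].shape
        self.net_config = net_config
        self.encode_config = encode_config
        self.loss_weights = loss_weights
        self.train_config = train_config

    @classmethod
    def from_manifest(cls, manifest_path, input_size: tuple[int, int] | None = None,
                      **kwargs) -> "IrisLocalizationModel":
        from .core import iter_samples
        samples = list(iter_samples(manifest_path))
        if input_size is not None:
            samples = [preprocess_sample(s, input_size) for s in samples]
        return cls(samples, **kwargs)

    # -- training ----------------------------------------------------------
    def fit(self, epochs: int | None = None, seed: int | None = None,
            verbose: bool = False) -> "IrisLocalizationResults":
        tc = self.train_config
        if epochs is not None:
            tc = replace(tc, epochs=epochs)
        if seed is not None:
            tc = replace(tc, seed=seed)
        rng = np.random.default_rng(tc.seed)
        net = IrisNet(self.net_config, seed=int(rng.integers(2**31)))
        opt = Adam(net.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)

        n = len(self.samples)
        order = rng.permutation(n)
        n_val = int(round(tc.val_fraction * n))
        val_idx = sorted(order[:n_val].tolist())
        train_idx = order[n_val:].tolist()
        if not train_idx:
            raise ValueError("validation split leaves no training samples")

        targets = [encode_sample(s.inner, s.outer, s.shape, self.encode_config)
                   for s in self.samples]
        inputs = np.stack([image_to_input(s.image) for s in self.samples])

        history: list[dict] = []
        best = {"miou": -1.0, "state": None, "epoch": -1}
        plateau_best, plateau_wait = np.inf, 0
        base_lr, global_step = tc.lr, 0

        for epoch in range(tc.epochs):
            net.train()
            rng.shuffle(train_idx)
            sums = {"cls": 0.0, "size": 0.0, "off": 0.0, "mask": 0.0, "total": 0.0}
            n_batches = 0
            for start in range(0, len(train_idx), tc.batch_size):
                batch = train_idx[start:start + tc.batch_size]
                parts = self._step(net, batch, inputs, targets, tc)
                opt.zero_grad()
                parts["total_t"].backward()
                # the focal loss is huge at initialization; warmup and
                # clipping keep Adam's moment estimates sane early on
                if tc.grad_clip > 0:
                    _clip_grad_norm(opt.params, tc.grad_clip)
                if global_step < tc.warmup_steps:
                    opt.lr = base_lr * (global_step + 1) / tc.warmup_steps
                elif global_step == tc.warmup_steps:
                    opt.lr = base_lr
                opt.step()
                global_step += 1
                for key in sums:
                    sums[key] += parts[key]
                n_batches += 1
            record = {k: v / n_batches for k, v in sums.items()}
            record["epoch"] = epoch
            record["lr"] = opt.lr

            if not np.isfinite(record["total"]):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: {record}; aborting. Last "
                    f"batch indices: {batch}"
                )

            net.eval()
            monitor = record["total"]
            if val_idx:
                val_miou, val_loss = self._validate(net, val_idx, inputs, targets, tc)
                record["val_miou_box_avg"] = val_miou
                record["val_loss"] = val_loss
                monitor = val_loss
            else:
                val_miou = -record["total"]
            if val_miou > best["miou"]:
                best = {"miou": val_miou, "epoch": epoch,
                        "state": copy.deepcopy(net.state_arrays())}

            if monitor < plateau_best - 1e-6:
                plateau_best, plateau_wait = monitor, 0
            else:
                plateau_wait += 1
                if plateau_wait > tc.lr_patience:
                    opt.lr *= tc.lr_factor
                    plateau_wait = 0
                    logger.info("epoch %d: lr reduced to %.2e", epoch, opt.lr)

            history.append(record)
            if verbose:
                logger.info("epoch %d: %s", epoch, record)

        if best["state"] is not None:
            net.load_state_arrays(best["state"])
        net.eval()
        return IrisLocalizationResults(
            net=net, model=self, train_config=tc,
            history=pd.DataFrame(history), best_epoch=best["epoch"],
            val_indices=val_idx,
            val_miou_box_avg=(best["miou"] if val_idx else float("nan")),
        )

    def _step(self, net: IrisNet, batch: list[int], inputs: np.ndarray,
              targets, tc: TrainConfig) -> dict:
        """One forward/loss pass; returns tensors and float components."""
        x = Tensor(inputs[batch])
        out = net.forward(x)
        heat = permute(out["heat"], (0, 2, 3, 1))
        radius = permute(out["radius"], (0, 2, 3, 1))
        offset = permute(out["offset"], (0, 2, 3, 1))
        gt_heat = np.stack([targets[i].heat for i in batch])
        gt_radius = np.stack([targets[i].radius for i in batch])
        gt_offset = np.stack([targets[i].offset for i in batch])
        pos_mask = np.stack([targets[i].pos_mask for i in batch])
        center_mask = np.stack([targets[i].center_mask for i in batch])

        cls = L.focal_loss(heat, gt_heat)
        size = L.size_loss(radius, gt_radius,
                           pos_mask if tc.size_mode == "all_pos" else center_mask,
                           mode=tc.size_mode)
        off = L.offset_loss(offset, gt_offset, center_mask)
        reg = L.reg_loss(size, off, self.loss_weights)

        # mask branch: RoI at the ground-truth outer circle during training
        mask_terms = []
        for j, i in enumerate(batch):
            sample = self.samples[i]
            patch, (y0, x0, side) = crop_roi_batch(
                out["feature"], j, sample.outer, self.net_config.crop_scale)
            probs = net.mask_head(patch)
            s3 = probs.shape[-1]
            gt_roi = _nearest_resize(
                _crop_pad_2d(sample.mask.astype(np.float32), y0, x0, side), s3)
            mask_terms.append(L.mask_loss(probs, gt_roi[None, None]))
        mask_l = mask_terms[0]
        for t in mask_terms[1:]:
            mask_l = mask_l + t
        mask_l = mask_l / len(mask_terms)

        total = L.total_loss(cls, reg, mask_l, self.loss_weights)
        return {"total_t": total, "cls": cls.item(), "size": size.item(),
                "off": off.item(), "mask": mask_l.item(), "total": total.item()}

    def _validate(self, net: IrisNet, val_idx, inputs, targets, tc) -> tuple[float, float]:
        mious, loss = [], 0.0
        for i in val_idx:
            parts = self._step(net, [i], inputs, targets, tc)
            loss += parts["total"]
            pred = net.predict_maps(self.samples[i].image)
            inner, outer, _ = decode_circles(pred)
            mious.append(0.5 * (box_iou(inner, self.samples[i].inner)
                                + box_iou(outer, self.samples[i].outer)))
        return float(np.mean(mious)), loss / len(val_idx)


def _clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def crop_roi_batch(feature: Tensor, batch_index: int, outer: Circle,
                   crop_scale: float):
    """RoI crop of one batch element around a circle center."""
    from .nn import crop2d
    y0, x0, side = roi_rect((outer.x, outer.y), outer.r, crop_scale)
    return crop2d(feature, y0, x0, side, batch=batch_index), (y0, x0, side)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class IrisLocalizationResults:
    """Trained-model results: network weights, history, and evaluation API."""

    def __init__(self, net: IrisNet, model: IrisLocalizationModel | None,
                 train_config: TrainConfig, history: pd.DataFrame,
                 best_epoch: int, val_indices: list[int],
                 val_miou_box_avg: float,
                 encode_config: EncodeConfig | None = None,
                 loss_weights: L.LossWeights | None = None) -> None:
        self.net = net
        self.model = model
        self.train_config = train_config
        self.history = history
        self.best_epoch = best_epoch
        self.val_indices = val_indices
        self.val_miou_box_avg = val_miou_box_avg
        self.encode_config = encode_config or (model.encode_config if model else EncodeConfig())
        self.loss_weights = loss_weights or (model.loss_weights if model else L.LossWeights())

    # -- inference ----------------------------------------------------------
    def predict_one(self, image: np.ndarray) -> LocalizationResult:
        """Full inference for one (H, W, 3) uint8 image."""
        self.net.eval()
        maps = self.net.predict_maps(image)
        inner, outer, (s_in, s_out) = decode_circles(maps)
        feature = Tensor(maps.feature.transpose(2, 0, 1)[None])
        patch, rect = crop_roi(feature, (outer.x, outer.y), outer.r,
                               self.net.config.crop_scale)
        native = self.net.mask_head(patch).data[0, 0]
        probs = upsample_probs(native, rect[2])
        mask = assemble_mask(probs, rect, image.shape[:2])
        return LocalizationResult(inner=inner, outer=outer, score_inner=s_in,
                                  score_outer=s_out, mask=mask)

    def predict(self, images) -> list[LocalizationResult]:
        return [self.predict_one(np.asarray(img)) for img in images]

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, samples: list[EyeSample], oracle: bool = False,
                 R: int = 64, A: int = 360) -> tuple[EvalReport, pd.DataFrame]:
        """Decode every sample and compute the full metric set.

        With ``oracle=True`` the ground truth is evaluated against itself,
        which checks the metric pipeline (all IoUs 1, all errors 0).
        """
        rows = []
        for sample in samples:
            if oracle:
                pred_inner, pred_outer, pred_mask = sample.inner, sample.outer, sample.mask
            else:
                res = self.predict_one(sample.image)
                pred_inner, pred_outer, pred_mask = res.inner, res.outer, res.mask
            rows.append({
                "name": sample.name,
                "iou_box_inner": box_iou(pred_inner, sample.inner),
                "iou_box_outer": box_iou(pred_outer, sample.outer),
                "hdist_inner": norm_hausdorff(pred_inner, sample.inner, sample.shape),
                "hdist_outer": norm_hausdorff(pred_outer, sample.outer, sample.shape),
                "e1_mask": e1(pred_mask, sample.mask),
                "iou_mask": mask_iou(pred_mask, sample.mask),
                "e1_norm": e1_norm(pred_mask, (pred_inner, pred_outer),
                                   sample.mask, (sample.inner, sample.outer),
                                   R=R, A=A),
            })
        df = pd.DataFrame(rows)
        report = EvalReport(
            miou_box_inner=float(df["iou_box_inner"].mean()),
            miou_box_outer=float(df["iou_box_outer"].mean()),
            miou_box_avg=float((df["iou_box_inner"] + df["iou_box_outer"]).mean() / 2),
            mhdist_inner=float(df["hdist_inner"].mean()),
            mhdist_outer=float(df["hdist_outer"].mean()),
            e1_mask=float(df["e1_mask"].mean()),
            miou_mask=float(df["iou_mask"].mean()),
            e1_norm=float(df["e1_norm"].mean()),
            n_images=len(df),
        )
        return report, df

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Iris localization model — fit summary",
            "=" * 44,
            f"parameters          {self.net.n_parameters():,}",
            f"architecture        depth={self.net.config.depth}, "
            f"base={self.net.config.base_channels}, "
            f"feature={self.net.config.feature_channels}",
            f"concentric targets  {self.encode_config.use_cgr}",
            f"epochs run          {len(self.history)}",
            f"best epoch          {self.best_epoch}",
            f"val mIoU (box avg)  {self.val_miou_box_avg:.4f}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines.append(f"final losses        total={last['total']:.4f} "
                         f"cls={last['cls']:.4f} size={last['size']:.4f} "
                         f"off={last['off']:.4f} mask={last['mask']:.4f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Write weights (npz) plus a JSON sidecar with all configurations."""
        extra = {
            "encode": self.encode_config.to_dict(),
            "loss_weights": self.loss_weights.to_dict(),
            "train": self.train_config.to_dict(),
            "best_epoch": self.best_epoch,
            "val_indices": list(map(int, self.val_indices)),
            "val_miou_box_avg": self.val_miou_box_avg,
            "history": self.history.to_dict(orient="list"),
        }
        save_checkpoint(path, self.net, extra)

    @classmethod
    def load(cls, path) -> "IrisLocalizationResults":
        net, sidecar = load_checkpoint(path)
        return cls(
            net=net, model=None,
            train_config=TrainConfig(**sidecar.get("train", {})),
            history=pd.DataFrame(sidecar.get("history", {})),
            best_epoch=sidecar.get("best_epoch", -1),
            val_indices=sidecar.get("val_indices", []),
            val_miou_box_avg=sidecar.get("val_miou_box_avg", float("nan")),
            encode_config=EncodeConfig(**sidecar.get("encode", {})),
            loss_weights=L.LossWeights(**sidecar.get("loss_weights", {})),
        )
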