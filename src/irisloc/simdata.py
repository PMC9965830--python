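"""Seeded procedural generator of synthetic eye images with exact ground truth.

Two regimes are emulated. The eye-only regime fills the frame with skin and
sclera around a textured iris annulus and a dark, possibly de-centered pupil.
The distractor regime additionally scatters dark face-like blobs (brow,
nostril, chin shadows) far from the eye, so the eye occupies a minor part of
the frame and a center detector can be misled — the situation the concentric
sampling strategy targets.

Noise sources, each applied with a configurable probability: an elliptical
eyelid occluder clipped from the top, specular highlight disks, and Gaussian
blur. Ground-truth masks are rasterized hard (pixel-center-in-circle) from
the exact circles so metric tests have integer-exact expectations, while the
rendered image uses anti-aliased edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Circle, EyeSample, INNER, OUTER, write_manifest, write_sample

__all__ = ["SimConfig", "sample_annotation", "render_eye", "make_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Radii are drawn as fractions: ``r_out_range`` of ``min(H, W)`` for the
    iris, ``pupil_ratio_range`` of the drawn outer radius for the pupil. The
    pupil center is jittered up to ``center_jitter_px`` from the iris center
    (re-drawn until the pupil lies strictly inside the iris).
    """

    image_size: tuple[int, int] = (96, 96)
    r_out_range: tuple[float, float] = (0.18, 0.30)
    pupil_ratio_range: tuple[float, float] = (0.25, 0.45)
    center_jitter_px: float = 2.0
    occlusion_prob: float = 0.3
    highlight_prob: float = 0.5
    blur_prob: float = 0.3
    distractors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h % 32 or w % 32:
            raise ValueError(f"image size {self.image_size} must be multiples of 32")
        if not (0.0 < self.pupil_ratio_range[0] <= self.pupil_ratio_range[1] < 1.0):
            raise ValueError("pupil_ratio_range must lie inside (0, 1)")
        if self.r_out_range[0] > self.r_out_range[1]:
            raise ValueError("empty r_out_range")

    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "r_out_range": list(self.r_out_range),
            "pupil_ratio_range": list(self.pupil_ratio_range),
            "center_jitter_px": self.center_jitter_px,
            "occlusion_prob": self.occlusion_prob,
            "highlight_prob": self.highlight_prob,
            "blur_prob": self.blur_prob,
            "distractors": self.distractors,
            "seed": self.seed,
        }


def sample_annotation(rng: np.random.Generator, cfg: SimConfig) -> tuple[Circle, Circle]:
    """Draw one (inner, outer) circle pair respecting the geometry invariants."""
    h, w = cfg.image_size
    scale = min(h, w)
    r_out = rng.uniform(*cfg.r_out_range) * scale
    if 2 * r_out >= min(h, w):
        raise ValueError("r_out_range too large for the image: no valid placement")
    cx = rng.uniform(r_out, w - r_out)
    cy = rng.uniform(r_out, h - r_out)
    r_in = rng.uniform(*cfg.pupil_ratio_range) * r_out
    while True:
        jx = rng.uniform(-cfg.center_jitter_px, cfg.center_jitter_px)
        jy = rng.uniform(-cfg.center_jitter_px, cfg.center_jitter_px)
        if np.hypot(jx, jy) + r_in < r_out:
            break
    inner = Circle(cx + jx, cy + jy, r_in, INNER)
    outer = Circle(cx, cy, r_out, OUTER)
    return inner, outer


def _soft_disk(d: np.ndarray, r: float) -> np.ndarray:
    """Anti-aliased disk indicator from a distance field (1 px soft edge)."""
    return np.clip(r + 0.5 - d, 0.0, 1.0)


def _paint(img: np.ndarray, alpha: np.ndarray, color: tuple) -> None:
    img *= (1.0 - alpha)[..., None]
    img += alpha[..., None] * np.asarray(color, dtype=np.float32)


def render_eye(inner: Circle, outer: Circle, rng: np.random.Generator,
               cfg: SimConfig) -> EyeSample:
    """Render one sample; the mask is the hard annulus minus occluded pixels."""
    h, w = cfg.image_size
    ys, xs = np.mgrid[:h, :w].astype(np.float32)
    d_out = np.hypot(xs - outer.x, ys - outer.y)
    d_in = np.hypot(xs - inner.x, ys - inner.y)

    # skin/sclera background: bright with a gentle gradient and grain
    base = 195.0 + 15.0 * (xs / w - 0.5) + rng.normal(0, 4, (h, w)).astype(np.float32)
    img = np.stack([base + 10, base - 5, base - 15], axis=-1)

    if cfg.distractors:
        # dark face-like blobs (brow/nostril/chin shadows) far from the eye
        for _ in range(int(rng.integers(2, 5))):
            for _attempt in range(50):
                bx = rng.uniform(0, w)
                by = rng.uniform(0, h)
                if np.hypot(bx - outer.x, by - outer.y) > 2.2 * outer.r:
                    break
            else:
                continue
            ax_ = rng.uniform(0.3, 1.2) * outer.r
            ay_ = rng.uniform(0.3, 1.2) * outer.r
            blob_d = np.hypot((xs - bx) / max(ax_, 1.0), (ys - by) / max(ay_, 1.0))
            shade = rng.uniform(60, 120)
            _paint(img, np.clip(1.2 - blob_d, 0, 1).astype(np.float32) * 0.9,
                   (shade, shade * 0.85, shade * 0.8))

    # iris annulus: radial + angular sinusoid texture over a brown base
    theta = np.arctan2(ys - outer.y, xs - outer.x)
    tex = (
        18.0 * np.sin(d_out * rng.uniform(0.8, 1.6) + rng.uniform(0, 6.28))
        + 14.0 * np.sin(theta * int(rng.integers(6, 14)) + rng.uniform(0, 6.28))
        + rng.normal(0, 6, (h, w))
    ).astype(np.float32)
    iris_alpha = _soft_disk(d_out, outer.r)
    _paint(img, iris_alpha, (118, 86, 60))
    img += (iris_alpha * tex)[..., None] * np.array([1.0, 0.9, 0.7], np.float32)

    # pupil: dark disk
    _paint(img, _soft_disk(d_in, inner.r), (28, 22, 22))

    # hard ground-truth annulus, pixel-center-in-circle rule
    mask = ((d_out <= outer.r) & (d_in > inner.r)).astype(np.uint8)

    if rng.uniform() < cfg.occlusion_prob:
        # elliptical eyelid clipped from the top of the iris
        lid_cy = outer.y - outer.r * rng.uniform(0.9, 1.3)
        lid_rx = outer.r * rng.uniform(1.4, 2.0)
        lid_ry = outer.r * rng.uniform(0.9, 1.3)
        lid = ((xs - outer.x) / lid_rx) ** 2 + ((ys - lid_cy) / lid_ry) ** 2 <= 1.0
        _paint(img, lid.astype(np.float32), (205, 180, 168))
        mask[lid] = 0

    if rng.uniform() < cfg.highlight_prob:
        for _ in range(int(rng.integers(1, 3))):
            hr = outer.r * rng.uniform(0.08, 0.18)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.0, 0.8) * outer.r
            hx, hy = outer.x + rad * np.cos(ang), outer.y + rad * np.sin(ang)
            d_h = np.hypot(xs - hx, ys - hy)
            _paint(img, _soft_disk(d_h, hr), (250, 250, 250))
            mask[d_h <= hr] = 0

    if rng.uniform() < cfg.blur_prob:
        img = gaussian_filter(img, sigma=(1.0, 1.0, 0.0))

    image = np.clip(img, 0, 255).astype(np.uint8)
    return EyeSample(image=image, inner=inner, outer=outer, mask=mask)


def generate_samples(n: int, cfg: SimConfig) -> list[EyeSample]:
    """Generate ``n`` samples, fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(n):
        inner, outer = sample_annotation(rng, cfg)
        sample = render_eye(inner, outer, rng, cfg)
        sample.name = f"sim_{i:04d}"
        samples.append(sample)
    return samples


def make_dataset(n: int, cfg: SimConfig, out_dir) -> Path:
    """Write ``n`` samples (PNG image + JSON annotation + PNG mask) and a
    manifest CSV with paths relative to the output directory; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_samples(n, cfg):
        stem = sample.name
        paths = {"image": f"{stem}.png", "annotation": f"{stem}.json",
                 "mask": f"{stem}_mask.png"}
        write_sample(sample, out / paths["image"], out / paths["annotation"],
                     out / paths["mask"])
        rows.append(paths)
    manifest = out / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest


def eye_frame_fraction(outer: Circle, image_size: tuple[int, int]) -> float:
    """Fraction of the frame covered by the eye's circumscribing square."""
    h, w = image_size
    return (2 * outer.r) ** 2 / (h * w)
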