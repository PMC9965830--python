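"""Domain types, circle geometry, coordinate conventions, and sample I/O.

Coordinate convention used throughout the package: ``x`` indexes columns and
``y`` indexes rows, both 0-based, with pixel centers at integer coordinates.
Arrays are stored row-major as ``(H, W)`` or ``(H, W, C)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Circle",
    "BBox",
    "EyeSample",
    "circle_bbox",
    "point_in_circle",
    "read_sample",
    "write_sample",
    "read_manifest",
    "write_manifest",
    "ValidationError",
]

INNER = "inner"
OUTER = "outer"
_CATEGORIES = (INNER, OUTER)


class ValidationError(ValueError):
    """An input file or annotation violates a structural invariant."""


@dataclass(frozen=True)
class Circle:
    """A circle in image pixel units.

    Parameters
    ----------
    x, y : float
        Center, as column (x) and row (y) coordinates.
    r : float
        Radius in pixels, strictly positive.
    category : str
        Either ``"inner"`` (pupil boundary) or ``"outer"`` (limbic boundary).
    """

    x: float
    y: float
    r: float
    category: str = INNER

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"circle radius must be > 0, got {self.r}")
        if self.category not in _CATEGORIES:
            raise ValueError(f"category must be one of {_CATEGORIES}, got {self.category!r}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)

    def translated(self, dx: float, dy: float) -> "Circle":
        return Circle(self.x + dx, self.y + dy, self.r, self.category)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in pixel coordinates, ``x_min < x_max``, ``y_min < y_max``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class EyeSample:
    """One annotated eye image: RGB pixels, two circles, and a binary iris mask."""

    image: np.ndarray  # (H, W, 3) uint8
    inner: Circle
    outer: Circle
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def validate(self) -> None:
        img, mask = np.asarray(self.image), np.asarray(self.mask)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValidationError(f"image must be (H, W, 3), got {img.shape}")
        if mask.shape != img.shape[:2]:
            raise ValidationError(
                f"mask shape {mask.shape} does not match image {img.shape[:2]}"
            )
        if not np.isin(mask, (0, 1)).all():
            raise ValidationError("mask must contain only 0/1 values")
        if not self.inner.r < self.outer.r:
            raise ValidationError(
                f"inner radius {self.inner.r} must be smaller than outer {self.outer.r}"
            )
        if not point_in_circle(self.inner.x, self.inner.y, self.outer):
            raise ValidationError("inner center lies outside the outer circle")
        ys, xs = np.nonzero(mask)
        if ys.size:
            d2 = (xs - self.outer.x) ** 2 + (ys - self.outer.y) ** 2
            # allow half-pixel slack for rasterized boundaries
            if d2.max() > (self.outer.r + 0.5) ** 2:
                raise ValidationError("mask pixels found outside the outer circle")


def circle_bbox(c: Circle) -> BBox:
    """Square box circumscribing a circle: ``[x-r, y-r, x+r, y+r]``."""
    if not c.r > 0:
        raise ValueError(f"radius must be positive, got {c.r}")
    return BBox(c.x - c.r, c.y - c.r, c.x + c.r, c.y + c.r)


def point_in_circle(px: float, py: float, c: Circle) -> bool:
    """True iff the point lies inside or on the circle (boundary inclusive)."""
    return (px - c.x) ** 2 + (py - c.y) ** 2 <= c.r**2


def disk_mask(c: Circle, shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) raster of the filled disk, pixel-center-in-circle rule."""
    h, w = shape
    ys, xs = np.ogrid[:h, :w]
    return (xs - c.x) ** 2 + (ys - c.y) ** 2 <= c.r**2


# ---------------------------------------------------------------------------
# Sample I/O: PNG/JPEG image + JSON annotation + PNG mask, plus a CSV manifest.
# ---------------------------------------------------------------------------

def _circle_from_json(d: dict, category: str, path: str) -> Circle:
    for key in ("x", "y", "r"):
        if key not in d:
            raise ValidationError(f"{path}: annotation {category!r} missing key {key!r}")
    return Circle(float(d["x"]), float(d["y"]), float(d["r"]), category)


def read_sample(image_path, annotation_path, mask_path) -> EyeSample:
    """Load one sample; the mask PNG is thresholded at 128 to binary {0, 1}."""
    image = np.asarray(iio.imread(image_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    image = image[..., :3]

    with open(annotation_path) as fh:
        ann = json.load(fh)
    for key in (INNER, OUTER):
        if key not in ann:
            raise ValidationError(f"{annotation_path}: missing key {key!r}")
    inner = _circle_from_json(ann[INNER], INNER, str(annotation_path))
    outer = _circle_from_json(ann[OUTER], OUTER, str(annotation_path))

    mask_raw = np.asarray(iio.imread(mask_path))
    if mask_raw.ndim == 3:
        mask_raw = mask_raw[..., 0]
    mask = (mask_raw >= 128).astype(np.uint8)

    try:
        return EyeSample(image=image.astype(np.uint8), inner=inner, outer=outer,
                         mask=mask, name=Path(image_path).stem)
    except ValidationError as err:
        raise ValidationError(f"{annotation_path}: {err}") from err


def write_sample(sample: EyeSample, image_path, annotation_path, mask_path) -> None:
    """Write image (PNG/JPEG), annotation JSON, and 0/255 mask PNG."""
    iio.imwrite(image_path, sample.image.astype(np.uint8))
    ann = {
        c.category: {"x": float(c.x), "y": float(c.y), "r": float(c.r)}
        for c in (sample.inner, sample.outer)
    }
    with open(annotation_path, "w") as fh:
        json.dump(ann, fh, indent=1, sort_keys=True)
        fh.write("\n")
    iio.imwrite(mask_path, (sample.mask.astype(np.uint8) * 255))


MANIFEST_COLUMNS = ("image", "annotation", "mask")


def write_manifest(rows: Sequence[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in MANIFEST_COLUMNS})


def read_manifest(path) -> list[dict]:
    base = Path(path).parent
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        for key in MANIFEST_COLUMNS:
            if key not in row:
                raise ValidationError(f"{path}: manifest missing column {key!r}")
            if not Path(row[key]).is_absolute():
                row[key] = str(base / row[key])
    return rows


def iter_samples(manifest_path) -> Iterator[EyeSample]:
    for row in read_manifest(manifest_path):
        yield read_sample(row["image"], row["annotation"], row["mask"])
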