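"""Rubber-sheet normalization of the iris annulus to a fixed polar grid.

The homogeneous rubber-sheet model maps the (possibly non-concentric)
annulus between the pupil and limbic circles to a rectangle: for each angle
θ the sample point interpolates linearly between the inner boundary point
and the outer boundary point, so irises with different sizes and pupil
dilations align on the same R x A grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import Circle

__all__ = ["PolarGrid", "rubber_sheet"]


@dataclass
class PolarGrid:
    """R x A sample grid: rows index the radial coordinate (0 = inner
    boundary, R-1 = outer boundary), columns the angle (θ = 2πj/A,
    counter-clockwise from the +x axis)."""

    data: np.ndarray
    R: int
    A: int

    def __post_init__(self) -> None:
        if self.R < 2 or self.A < 2:
            raise ValueError("polar grid needs R, A >= 2")
        if self.data.shape != (self.R, self.A):
            raise ValueError(f"grid data {self.data.shape} != ({self.R}, {self.A})")

    def save_png(self, path, mask: bool = True) -> None:
        """Write the grid as a PNG, A pixels wide by R tall; mask grids are
        binarized at 0.5 to 0/255, texture grids written as 8-bit gray."""
        import imageio.v3 as iio

        if mask:
            img = ((self.data >= 0.5) * 255).astype(np.uint8)
        else:
            img = np.clip(self.data, 0, 255).astype(np.uint8)
        iio.imwrite(path, img)


def rubber_sheet(source: np.ndarray, inner: Circle, outer: Circle,
                 R: int = 64, A: int = 360, inset: float = 0.5) -> PolarGrid:
    """Unwrap ``source`` between the two circles to an R x A polar grid.

    Sample points are ``P(ρ, θ) = (1-ρ)·B_in(θ) + ρ·B_out(θ)`` where ``B_in``
    and ``B_out`` are the circle boundary points at angle θ and ρ runs over
    ``i/(R-1)``. The boundary rays are inset by ``inset`` pixels at each end
    (default half a pixel), so row 0 samples the first ring of pixel centers
    just outside the inner circle rather than the aliased boundary itself;
    with ``inset=0`` the boundaries are sampled exactly. Values are read with
    bilinear interpolation; points outside the image read 0.
    """
    src = np.asarray(source, dtype=np.float64)
    if src.ndim != 2:
        raise ValueError("source must be a 2-D array")
    # the inner circle must lie strictly inside the outer one
    d = np.hypot(inner.x - outer.x, inner.y - outer.y)
    if d + inner.r >= outer.r:
        raise ValueError("inner circle is not strictly inside the outer circle")

    theta = 2.0 * np.pi * np.arange(A) / A
    rho = (np.arange(R) / (R - 1))[:, None]
    bx_in = inner.x + inner.r * np.cos(theta)
    by_in = inner.y + inner.r * np.sin(theta)
    bx_out = outer.x + outer.r * np.cos(theta)
    by_out = outer.y + outer.r * np.sin(theta)
    if inset:
        ray = np.hypot(bx_out - bx_in, by_out - by_in)
        t0 = np.minimum(inset / ray, 0.5)
        rho = t0 + rho * (1.0 - 2.0 * t0)
    xs = (1.0 - rho) * bx_in + rho * bx_out
    ys = (1.0 - rho) * by_in + rho * by_out
    grid = map_coordinates(src, [ys, xs], order=1, mode="constant", cval=0.0)
    return PolarGrid(data=grid, R=R, A=A)
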