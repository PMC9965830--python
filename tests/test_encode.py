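"""Heatmap/target encoding, including the concentric-region strategy."""

import math

import numpy as np
import pytest

from irisloc.core import Circle, disk_mask
from irisloc.encode import (EncodeConfig, build_heatmaps,
                            build_regression_targets, encode_sample,
                            gaussian_sigma, render_gaussian)

from conftest import random_annotation


# ---------------------------------------------------------------------------
# adaptive Gaussian width
# ---------------------------------------------------------------------------

def _worst_case_iou(side: float, g: float) -> float:
    """Worst box IoU over the three displacement cases at placement radius g."""
    w = h = side
    shifted = (w - g) * (h - g) / (2 * w * h - (w - g) * (h - g))
    inward = (w - 2 * g) * (h - 2 * g) / (w * h) if min(w, h) > 2 * g else 0.0
    outward = w * h / ((w + 2 * g) * (h + 2 * g))
    return min(shifted, inward, outward)


def test_gaussian_sigma_matches_bruteforce_placement_radius():
    """sigma*3 equals the largest displacement keeping IoU >= min_overlap,
    found by exhaustive search over integer displacements."""
    r, overlap = 20.0, 0.7
    best_g = 0
    for g in range(1, int(2 * r) + 1):
        if _worst_case_iou(2 * r, g) >= overlap:
            best_g = g
    sigma = gaussian_sigma(r, overlap)
    assert abs(3 * sigma - best_g) <= 1.0
    # and the analytic radius itself satisfies the IoU constraint
    assert _worst_case_iou(2 * r, 3 * sigma) >= overlap - 1e-9


def test_gaussian_sigma_monotonicity():
    # sigma grows with the radius ...
    radii = [4.0, 8.0, 16.0, 32.0]
    sigmas = [gaussian_sigma(r, 0.7) for r in radii]
    assert all(a < b for a, b in zip(sigmas, sigmas[1:]))
    # ... and shrinks as the required overlap tightens
    overlaps = [0.3, 0.5, 0.7, 0.9]
    sigmas_o = [gaussian_sigma(64.0, o) for o in overlaps]
    assert all(a > b for a, b in zip(sigmas_o, sigmas_o[1:]))
    # the optional floor binds only for tiny circles
    assert gaussian_sigma(4.0, 0.7, min_sigma=1.0) == 1.0
    assert gaussian_sigma(4.0, 0.7) < 0.5


def test_gaussian_sigma_rejects_degenerate():
    with pytest.raises(ValueError):
        gaussian_sigma(0.0, 0.7)
    with pytest.raises(ValueError):
        gaussian_sigma(5.0, 1.0)


# ---------------------------------------------------------------------------
# single-Gaussian rendering
# ---------------------------------------------------------------------------

def test_render_gaussian_peak_and_closed_form():
    heat = render_gaussian((30.0, 40.0), sigma=4.0, support=None, shape=(64, 64))
    assert heat[40, 30] == 1.0
    # value one sigma away along an axis
    assert heat[40, 34] == pytest.approx(math.exp(-0.5), abs=1e-6)


def test_render_gaussian_truncation():
    support = Circle(30, 40, 6.0)
    heat = render_gaussian((30.0, 40.0), sigma=4.0, support=support, shape=(64, 64))
    inside = disk_mask(support, (64, 64))
    assert (heat[~inside] == 0).all()
    assert heat[inside].max() == 1.0


def test_render_gaussian_center_outside_image():
    with pytest.raises(ValueError):
        render_gaussian((70.0, 10.0), 3.0, None, (64, 64))


# ---------------------------------------------------------------------------
# concentric-region heatmaps
# ---------------------------------------------------------------------------

def _cgr_scalar(y_in: float, y_out: float, cfg: EncodeConfig) -> float:
    """Independent scalar evaluation of the shared-value rule."""
    if y_in == 1.0 and y_out == 1.0:
        return 1.0
    if y_in == 0.0 or y_out == 0.0:
        return 0.0
    return min(cfg.clip_max,
               0.5 * (cfg.alpha_inner * y_in + cfg.alpha_outer * y_out))


def _cgr_channel(k: int, y_in: float, y_out: float, cfg: EncodeConfig) -> float:
    """Per-channel expectation: the shared value where both Gaussians are
    strictly positive, otherwise the channel's own truncated Gaussian
    (one Gaussian can underflow to exactly zero inside the support)."""
    if y_in > 0.0 and y_out > 0.0:
        return _cgr_scalar(y_in, y_out, cfg)
    return y_in if k == 0 else y_out


def test_cgr_shared_value_clips_at_half():
    # where both Gaussians are 0.9 the shared value saturates the clip
    assert _cgr_scalar(0.9, 0.9, EncodeConfig()) == 0.5
    assert _cgr_scalar(0.4, 0.2, EncodeConfig()) == pytest.approx(0.3)


def test_build_heatmaps_matches_scalar_rule(rng):
    """Away from the hard-coded peak/neighbor pixels, the built heatmap equals
    the scalar concentric rule applied to the two truncated Gaussians."""
    cfg = EncodeConfig()
    inner, outer = random_annotation(rng)
    shape = (96, 96)
    heat = build_heatmaps(inner, outer, shape, cfg)
    gaussians = []
    for circ in (inner, outer):
        sigma = gaussian_sigma(circ.r, cfg.min_overlap)
        gaussians.append(render_gaussian((circ.x, circ.y), sigma, inner, shape))
    override = np.zeros(shape, dtype=bool)
    for circ in (inner, outer):
        cx, cy = int(circ.x), int(circ.y)
        override[cy, cx] = True
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            override[cy + dy, cx + dx] = True
    for i in range(shape[0]):
        for j in range(shape[1]):
            if override[i, j]:
                continue
            y_in, y_out = gaussians[0][i, j], gaussians[1][i, j]
            for k in range(2):
                expected = _cgr_channel(k, y_in, y_out, cfg)
                assert heat[i, j, k] == pytest.approx(expected, abs=1e-6)


def test_heatmap_peaks_neighbors_and_clip(rng):
    cfg = EncodeConfig()
    for _ in range(25):
        inner, outer = random_annotation(rng)
        heat = build_heatmaps(inner, outer, (96, 96), cfg)
        assert heat.min() >= 0.0 and heat.max() <= 1.0
        for k, circ in enumerate((inner, outer)):
            cx, cy = int(circ.x), int(circ.y)
            assert heat[cy, cx, k] == 1.0
            neighbors = [heat[cy + 1, cx, k], heat[cy - 1, cx, k],
                         heat[cy, cx + 1, k], heat[cy, cx - 1, k]]
            assert neighbors == [0.8] * 4
            rest = heat[..., k].copy()
            rest[cy, cx] = 0
            rest[cy + 1, cx] = rest[cy - 1, cx] = 0
            rest[cy, cx + 1] = rest[cy, cx - 1] = 0
            assert rest.max() <= cfg.clip_max + 1e-6


def test_heatmap_support_limited_to_inner_circle(rng):
    for use_cgr in (True, False):
        cfg = EncodeConfig(use_cgr=use_cgr)
        inner, outer = random_annotation(rng)
        heat = build_heatmaps(inner, outer, (96, 96), cfg)
        inside = disk_mask(inner, (96, 96))
        # allow the hard-coded axis-neighbors of the centers
        for k, circ in enumerate((inner, outer)):
            cx, cy = int(circ.x), int(circ.y)
            inside[cy, cx] = True
            inside[cy - 1:cy + 2, cx] = True
            inside[cy, cx - 1:cx + 2] = True
        assert (heat[~inside] == 0).all()


def test_cgr_disabled_gives_truncated_gaussians(rng):
    cfg = EncodeConfig(use_cgr=False)
    inner, outer = random_annotation(rng)
    heat = build_heatmaps(inner, outer, (96, 96), cfg)
    for k, circ in enumerate((inner, outer)):
        cy, cx = np.unravel_index(heat[..., k].argmax(), heat.shape[:2])
        assert (cx, cy) == (int(circ.x), int(circ.y))
        # no hard-coded 0.8 neighbors in this mode
        sigma = gaussian_sigma(circ.r, cfg.min_overlap)
        expected = math.exp(-1.0 / (2 * sigma * sigma))
        assert heat[cy, cx + 1, k] == pytest.approx(expected, abs=1e-6)


def test_encode_is_deterministic(rng):
    inner, outer = random_annotation(rng)
    a = encode_sample(inner, outer, (96, 96))
    b = encode_sample(inner, outer, (96, 96))
    for field in ("heat", "radius", "offset", "pos_mask", "center_mask"):
        assert np.array_equal(getattr(a, field), getattr(b, field))


# ---------------------------------------------------------------------------
# regression targets
# ---------------------------------------------------------------------------

def test_offsets_are_fractional_parts():
    # distinct floored centers so each writes its own fractional offset
    inner = Circle(10.3, 20.0, 4.0, "inner")
    outer = Circle(11.5, 21.25, 12.0, "outer")
    tm = encode_sample(inner, outer, (64, 64))
    assert tm.offset[20, 10, 0] == pytest.approx(0.3)
    assert tm.offset[20, 10, 1] == pytest.approx(0.0)
    assert tm.offset[21, 11, 0] == pytest.approx(0.5)
    assert tm.offset[21, 11, 1] == pytest.approx(0.25)
    assert tm.center_mask[..., 0].sum() == 1
    assert tm.center_mask[..., 1].sum() == 1


def test_integer_center_zero_offset():
    inner = Circle(16.0, 20.0, 4.0, "inner")
    outer = Circle(16.0, 20.0, 12.0, "outer")
    tm = encode_sample(inner, outer, (64, 64))
    assert tm.offset[20, 16, 0] == 0.0 and tm.offset[20, 16, 1] == 0.0


def test_radius_constant_on_support(rng):
    inner, outer = random_annotation(rng)
    tm = encode_sample(inner, outer, (96, 96))
    for k, circ in enumerate((inner, outer)):
        pos = tm.pos_mask[..., k].astype(bool)
        assert pos.sum() > 0
        mean_r = tm.radius[..., k][pos].mean()
        assert mean_r == pytest.approx(circ.r, abs=1e-5)
        # positive-sample support is exactly where heat is positive
        assert np.array_equal(pos, tm.heat[..., k] > 0)
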