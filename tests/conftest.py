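"""Shared fixtures: seeded geometry and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from irisloc.core import Circle, INNER, OUTER
from irisloc.simdata import SimConfig, generate_samples


def random_annotation(rng: np.random.Generator, shape=(96, 96),
                      margin: float = 2.0) -> tuple[Circle, Circle]:
    """A valid (inner, outer) pair placed inside the image with a margin."""
    h, w = shape
    r_out = rng.uniform(10.0, 0.3 * min(h, w))
    cx = rng.uniform(r_out + margin, w - r_out - margin)
    cy = rng.uniform(r_out + margin, h - r_out - margin)
    r_in = rng.uniform(0.25, 0.6) * r_out
    while True:
        jx, jy = rng.uniform(-2, 2, size=2)
        if np.hypot(jx, jy) + r_in < r_out:
            break
    return (Circle(cx + jx, cy + jy, r_in, INNER),
            Circle(cx, cy, r_out, OUTER))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def eye_samples():
    """A dozen default-regime synthetic samples."""
    return generate_samples(12, SimConfig(seed=7))


@pytest.fixture(scope="session")
def clean_sample():
    """One sample without occlusion/highlight/blur (mask = exact annulus)."""
    cfg = SimConfig(seed=5, occlusion_prob=0.0, highlight_prob=0.0, blur_prob=0.0)
    return generate_samples(1, cfg)[0]
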