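"""Shared fixtures: rendered trees are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from baumtest.pipeline import measure_image
from baumtest.synthetic import SyntheticTreeSpec, render


def standard_spec(**overrides) -> SyntheticTreeSpec:
    """A mid-sized tree with roots at 150 dpi; override fields per test."""
    base = dict(
        crown_a_cm=3.0,
        crown_b_cm=2.5,
        trunk_top_width_cm=0.9,
        trunk_bottom_width_cm=1.1,
        trunk_height_cm=4.0,
        root_count=3,
        root_length_cm=2.0,
        style="filled",
        noise_sigma=0.0,
        annotation=False,
        dpi=150.0,
        seed=1,
    )
    base.update(overrides)
    return SyntheticTreeSpec(**base)


@pytest.fixture(scope="session")
def clean_render():
    """Noise-free filled tree: (spec, image, ground-truth seg, true metrics)."""
    spec = standard_spec()
    image, seg, metrics = render(spec)
    return spec, image, seg, metrics


@pytest.fixture(scope="session")
def noisy_render():
    """Outline tree with scanner noise and a margin annotation."""
    spec = standard_spec(style="outline", noise_sigma=8.0, annotation=True, seed=2)
    image, seg, metrics = render(spec)
    return spec, image, seg, metrics


@pytest.fixture(scope="session")
def measured_clean(clean_render):
    _, image, _, _ = clean_render
    return measure_image(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
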