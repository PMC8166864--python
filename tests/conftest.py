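"""Shared fixtures: small rendered phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pollenstack import synthetic as syn
from pollenstack.detection import detect_grains, extract_substack


@pytest.fixture(scope="session")
def urtica_params() -> syn.GrainPhantomParams:
    return syn.sample_grain("urtica", np.random.default_rng(11))


@pytest.fixture(scope="session")
def single_grain_scene(urtica_params):
    """One centred Urtica-like grain with mild noise; plus ground truth."""
    cfg = syn.SceneConfig(
        image_shape_px=(208, 208),
        grains=[syn.PlacedGrain(urtica_params, (104.0, 104.0))],
        noise_sd=3.0,
        seed=21,
    )
    stack, truth = syn.render_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def grain_stack(single_grain_scene):
    """The detected grain of the single-grain scene, cropped with margin."""
    _, stack, _ = single_grain_scene
    result = detect_grains(stack)
    assert len(result) == 1
    return extract_substack(stack, result[0], margin_px=8)
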