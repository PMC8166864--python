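"""Projection operators against brute-force oracles; framing contracts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from pollenstack.detection import GrainRegion, GrainStack
from pollenstack.projections import (
    compose_frame,
    edof_focus_scores,
    edof_projection,
    min_projection,
    project_grain,
    stddev_projection,
)


def _toy_grain_stack(voxels: np.ndarray, pixel_size_um: float = 0.16) -> GrainStack:
    """Wrap a bare array as a GrainStack with a centred circular region."""
    _, rows, cols = voxels.shape
    mask = np.zeros((rows, cols), dtype=bool)
    rr, cc = np.mgrid[:rows, :cols]
    mask[(rr - rows // 2) ** 2 + (cc - cols // 2) ** 2 <= (min(rows, cols) // 3) ** 2] = True
    region = GrainRegion(
        mask=mask,
        centroid=((rows - 1) / 2, (cols - 1) / 2),
        area_um2=float(mask.sum()) * pixel_size_um**2,
        equivalent_diameter_um=2 * np.sqrt(mask.sum() / np.pi) * pixel_size_um,
        perimeter_um=1.0,
        circularity=1.0,
        bbox=(0, 0, rows, cols),
    )
    return GrainStack(
        voxels=voxels, region=region, crop_origin=(0, 0), margin_px=0,
        pixel_size_um=pixel_size_um, z_step_um=1.8,
    )


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_stddev(voxels: np.ndarray) -> np.ndarray:
    """Per-pixel sample standard deviation via an explicit loop."""
    s, rows, cols = voxels.shape
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            vals = [float(voxels[k, r, c]) for k in range(s)]
            mean = sum(vals) / s
            out[r, c] = (sum((v - mean) ** 2 for v in vals) / (s - 1)) ** 0.5
    return out


def brute_min(voxels: np.ndarray) -> np.ndarray:
    s, rows, cols = voxels.shape
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            out[r, c] = min(voxels[k, r, c] for k in range(s))
    return out


def brute_edof_index(voxels: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel argmax of the per-slice focus score, computed independently."""
    scores = edof_focus_scores(voxels, focus_window_px=window, smoothing_px=0.0)
    s, rows, cols = voxels.shape
    out = np.empty((rows, cols), dtype=np.intp)
    for r in range(rows):
        for c in range(cols):
            best, best_k = -1.0, 0
            for k in range(s):
                if scores[k, r, c] > best:
                    best, best_k = scores[k, r, c], k
            out[r, c] = best_k
    return out


@pytest.mark.parametrize("seed", range(5))
def test_projections_match_brute_force_on_random_stacks(seed):
    rng = np.random.default_rng(seed)
    voxels = rng.random((5, 8, 8)) * 200
    gs = _toy_grain_stack(voxels)

    np.testing.assert_allclose(stddev_projection(gs), brute_stddev(voxels), rtol=1e-9)
    np.testing.assert_array_equal(min_projection(gs), brute_min(voxels))

    _, index_map = edof_projection(gs, focus_window_px=3, smoothing_px=0.0, return_index_map=True)
    np.testing.assert_array_equal(index_map, brute_edof_index(voxels, 3))


def test_stddev_two_values_hand_case():
    voxels = np.zeros((2, 4, 4))
    voxels[1, 2, 2] = 2.0
    gs = _toy_grain_stack(voxels)
    out = stddev_projection(gs)
    assert out[2, 2] == pytest.approx(np.sqrt(2.0))  # sd of {0, 2} with n-1
    assert out[0, 0] == 0.0


def test_stddev_requires_two_slices():
    with pytest.raises(ValueError, match="2 slices"):
        stddev_projection(_toy_grain_stack(np.zeros((1, 4, 4))))


def test_projections_invariant_under_slice_permutation():
    rng = np.random.default_rng(3)
    voxels = rng.random((6, 10, 10))
    permuted = voxels[rng.permutation(6)]
    np.testing.assert_allclose(
        stddev_projection(_toy_grain_stack(voxels)),
        stddev_projection(_toy_grain_stack(permuted)),
        rtol=1e-12,
    )
    np.testing.assert_array_equal(
        min_projection(_toy_grain_stack(voxels)),
        min_projection(_toy_grain_stack(permuted)),
    )


def test_min_projection_bounds_and_identity():
    rng = np.random.default_rng(4)
    voxels = rng.random((3, 6, 6))
    out = min_projection(_toy_grain_stack(voxels))
    assert (out <= voxels).all()
    single = min_projection(_toy_grain_stack(voxels[:1]))
    np.testing.assert_array_equal(single, voxels[0])


def test_edof_constant_stack_returns_constant():
    gs = _toy_grain_stack(np.full((4, 8, 8), 42.0))
    np.testing.assert_allclose(edof_projection(gs), 42.0)


def test_edof_selects_sharp_half_from_each_slice():
    """Slice 0 sharp left / slice 1 sharp right: the index map must split."""
    rng = np.random.default_rng(7)
    sharp = rng.random((24, 48)) * 100
    blurred = ndimage.gaussian_filter(sharp, 4.0)
    s0 = np.concatenate([sharp[:, :24], blurred[:, 24:]], axis=1)
    s1 = np.concatenate([blurred[:, :24], sharp[:, 24:]], axis=1)
    gs = _toy_grain_stack(np.stack([s0, s1]))
    _, index_map = edof_projection(gs, focus_window_px=3, smoothing_px=0.0, return_index_map=True)
    assert (index_map[:, :18] == 0).mean() > 0.95
    assert (index_map[:, 30:] == 1).mean() > 0.95


def test_edof_single_slice_identity():
    voxels = np.random.default_rng(5).random((1, 8, 8))
    np.testing.assert_array_equal(edof_projection(_toy_grain_stack(voxels)), voxels[0])


def test_edof_output_values_exist_in_pixel_columns():
    rng = np.random.default_rng(9)
    voxels = rng.random((5, 12, 12))
    gs = _toy_grain_stack(voxels)
    out = edof_projection(gs)
    matches = (voxels == out[np.newaxis]).any(axis=0)
    assert matches.all()


# ---------------------------------------------------------------------------
# framing
# ---------------------------------------------------------------------------

def test_compose_frame_places_content_centrally():
    voxels = np.random.default_rng(1).random((4, 100, 100)) + 0.5
    gs = _toy_grain_stack(voxels)
    frame = project_grain(gs)
    assert frame.pixels.shape == (276, 276, 3)
    # content window is the central 100x100 block
    off = frame.provenance["offset"]
    assert off == [88, 88]


def test_frame_preserves_grain_pixel_span(grain_stack):
    """No resampling: the grain's pixel diameter is unchanged by framing."""
    frame = project_grain(grain_stack)
    expected_px = grain_stack.region.equivalent_diameter_um / grain_stack.pixel_size_um
    # the normalised min channel has rim ~0, cytoplasm ~0.65, background ~1;
    # 0.8 separates the grain disc from the surround
    min_ch = frame.pixels[..., 1]
    dark = min_ch < 0.8
    measured_px = 2 * np.sqrt(dark.sum() / np.pi)
    assert abs(measured_px - expected_px) <= 4
    assert frame.pixel_size_um == grain_stack.pixel_size_um


def test_frame_centroid_at_centre(grain_stack):
    frame = project_grain(grain_stack)
    region = grain_stack.region
    off_r, off_c = frame.provenance["offset"]
    r0, c0 = grain_stack.crop_origin
    centroid_in_frame = (
        region.centroid[0] - r0 + off_r,
        region.centroid[1] - c0 + off_c,
    )
    assert abs(centroid_in_frame[0] - 137.5) <= 1.0
    assert abs(centroid_in_frame[1] - 137.5) <= 1.0


def test_oversized_projection_is_an_error():
    voxels = np.zeros((3, 277, 277))
    gs = _toy_grain_stack(voxels)
    with pytest.raises(ValueError, match="exceeds frame"):
        project_grain(gs)


def test_mismatched_projection_shapes_error(grain_stack):
    std = stddev_projection(grain_stack)
    mn = min_projection(grain_stack)
    with pytest.raises(ValueError, match="share a shape"):
        compose_frame(std, mn[:-1], mn, grain_stack)


def test_pipeline_is_deterministic(grain_stack):
    a = project_grain(grain_stack)
    b = project_grain(grain_stack)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_normalized_frame_invariant_under_intensity_rescaling(grain_stack):
    """Uniform gain before projection does not change the normalised frame."""
    scaled = dataclasses.replace(grain_stack, voxels=grain_stack.voxels * 1.7)
    a = project_grain(grain_stack)
    b = project_grain(scaled)
    np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-5)
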