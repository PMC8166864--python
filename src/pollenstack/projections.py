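"""The three stack projections and the fixed-size classifier frame.

A grain's focus-filtered sub-stack is collapsed into three 2-D images
that together act as the channels of the classifier input:

* **standard deviation** — per-pixel sample standard deviation through
  the stack (bright where intensity varies with depth, i.e. at walls,
  pores and ornamentation);
* **minimum intensity** — per-pixel minimum through the stack (the
  darkest rendition of every absorbing structure);
* **extended depth of field** — per pixel, the value from the slice
  where that pixel is sharpest, judged by local squared-gradient energy
  (hard slice selection, so every output value exists somewhere in the
  input column).

The three projections are then min–max normalised per channel and placed
*unscaled* into a 276x276 frame with the grain centroid at the centre:
grain size is a class feature, so resampling is never allowed and a
grain larger than the frame is an error.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .detection import GrainStack
from .stack_io import FRAME_PX, CHANNEL_ROLES, FramedImage


def stddev_projection(grain_stack: GrainStack, ddof: int = 1) -> np.ndarray:
    """Per-pixel sample standard deviation (n-1 denominator) over slices."""
    if grain_stack.n_slices < 2:
        raise ValueError(
            "standard-deviation projection needs >= 2 slices; "
            "relax the focus filter's min_kept_slices"
        )
    return np.std(grain_stack.voxels.astype(np.float64), axis=0, ddof=ddof)


def min_projection(grain_stack: GrainStack) -> np.ndarray:
    """Per-pixel minimum intensity over slices."""
    if grain_stack.n_slices < 1:
        raise ValueError("empty stack")
    return grain_stack.voxels.min(axis=0)


def edof_focus_scores(
    voxels: np.ndarray,
    focus_window_px: int = 5,
    smoothing_px: float = 2.0,
) -> np.ndarray:
    """Per-slice, per-pixel focus score: local squared-gradient energy.

    The squared Sobel gradient magnitude is averaged over a
    ``focus_window_px`` neighbourhood, then the score maps are smoothed
    with a Gaussian of ``smoothing_px`` to regularise the slice-index map.
    """
    scores = np.empty_like(voxels, dtype=np.float64)
    for i, sl in enumerate(voxels.astype(np.float64)):
        gr = ndimage.sobel(sl, axis=0, mode="nearest")
        gc = ndimage.sobel(sl, axis=1, mode="nearest")
        energy = gr**2 + gc**2
        energy = ndimage.uniform_filter(energy, size=focus_window_px, mode="nearest")
        if smoothing_px > 0:
            energy = ndimage.gaussian_filter(energy, smoothing_px, mode="nearest")
        scores[i] = energy
    return scores


def edof_projection(
    grain_stack: GrainStack,
    focus_window_px: int = 5,
    smoothing_px: float = 2.0,
    return_index_map: bool = False,
):
    """Extended-depth-of-field composite by hard per-pixel slice selection."""
    if grain_stack.n_slices < 1:
        raise ValueError("empty stack")
    voxels = grain_stack.voxels
    if grain_stack.n_slices == 1:
        out = voxels[0].copy()
        return (out, np.zeros(out.shape, dtype=np.intp)) if return_index_map else out
    scores = edof_focus_scores(voxels, focus_window_px, smoothing_px)
    index_map = np.argmax(scores, axis=0)
    out = np.take_along_axis(voxels, index_map[np.newaxis], axis=0)[0]
    return (out, index_map) if return_index_map else out


def _normalize(channel: np.ndarray) -> np.ndarray:
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        return np.zeros_like(channel, dtype=np.float64)
    return (channel.astype(np.float64) - lo) / (hi - lo)


def _border_median(channel: np.ndarray) -> float:
    border = np.concatenate(
        [channel[0, :], channel[-1, :], channel[1:-1, 0], channel[1:-1, -1]]
    )
    return float(np.median(border))


def compose_frame(
    stddev: np.ndarray,
    min_int: np.ndarray,
    edof: np.ndarray,
    grain_stack: GrainStack,
    frame_px: int = FRAME_PX,
) -> FramedImage:
    """Normalise the three projections and centre them in the fixed frame.

    Each channel is min–max normalised to [0, 1] independently, placed
    without resampling with the grain centroid at the frame centre, and
    padded with the channel's background estimate (median of its border
    pixels).  Physical scale is inherited unchanged.
    """
    shape = stddev.shape
    if min_int.shape != shape or edof.shape != shape:
        raise ValueError("the three projections must share a shape")
    if shape[0] > frame_px or shape[1] > frame_px:
        raise ValueError(
            f"grain exceeds frame: projection {shape} does not fit in "
            f"{frame_px}x{frame_px}; grains are never downscaled"
        )
    region = grain_stack.region
    r_origin, c_origin = grain_stack.crop_origin
    cen_r = region.centroid[0] - r_origin
    cen_c = region.centroid[1] - c_origin
    # integer placement offset putting the centroid at the frame centre
    center = (frame_px - 1) / 2.0
    off_r = int(round(center - cen_r))
    off_c = int(round(center - cen_c))
    off_r = min(max(off_r, 0), frame_px - shape[0])
    off_c = min(max(off_c, 0), frame_px - shape[1])

    frame = np.empty((frame_px, frame_px, 3), dtype=np.float32)
    for k, channel in enumerate((stddev, min_int, edof)):
        norm = _normalize(channel)
        frame[..., k] = _border_median(norm)
        frame[off_r : off_r + shape[0], off_c : off_c + shape[1], k] = norm
    return FramedImage(
        pixels=frame,
        pixel_size_um=grain_stack.pixel_size_um,
        channel_roles=CHANNEL_ROLES,
        provenance={
            "crop_origin": list(grain_stack.crop_origin),
            "bbox": list(region.bbox),
            "n_slices": grain_stack.n_slices,
            "offset": [off_r, off_c],
            "normalization": "per-channel min-max",
        },
    )


def project_grain(
    grain_stack: GrainStack,
    focus_window_px: int = 5,
    smoothing_px: float = 2.0,
    frame_px: int = FRAME_PX,
) -> FramedImage:
    """Convenience: all three projections plus framing in one call."""
    return compose_frame(
        stddev_projection(grain_stack),
        min_projection(grain_stack),
        edof_projection(grain_stack, focus_window_px, smoothing_px),
        grain_stack,
        frame_px=frame_px,
    )
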