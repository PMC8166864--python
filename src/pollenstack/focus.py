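"""Removal of out-of-focus slices from a grain's sub-stack.

An in-focus brightfield slice of a stained grain contains both deep
shadows (the exine rim) and a bright surround; defocus pulls both
extremes toward the mid-grey background.  A slice is therefore kept when
its minimum intensity is at or below ``min_pixel_threshold`` AND its
maximum is at or above ``max_pixel_threshold``.  Statistics are computed
inside the grain mask dilated by the crop margin, so neighbouring
structures do not leak into the decision.

Absolute thresholds depend on bit depth and staining, so the default is
calibration-free: the thresholds are placed at percentiles of the
stack's own per-slice extrema (``min <= P25`` of the slice minima,
``max >= P75`` of the slice maxima).  If filtering would leave fewer
than ``min_kept_slices`` slices (debris-occluded grains), the best
slices by contrast are kept instead and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import GrainStack

log = logging.getLogger(__name__)


@dataclass
class FocusParams:
    """Keep-rule thresholds for slice filtering."""

    min_pixel_threshold: float
    max_pixel_threshold: float
    min_kept_slices: int = 3

    # note: the two thresholds bound *different* statistics (per-slice min
    # and max), so no ordering between them is required — a vacuously
    # permissive setting is (+inf, 0), which keeps every slice
    def __post_init__(self) -> None:
        if self.min_kept_slices < 1:
            raise ValueError("min_kept_slices must be >= 1")


def _stats_mask(grain_stack: GrainStack) -> np.ndarray:
    mask = grain_stack.mask_in_crop()
    if grain_stack.margin_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=grain_stack.margin_px)
    if not mask.any():  # degenerate region: fall back to the whole crop
        mask = np.ones(grain_stack.voxels.shape[1:], dtype=bool)
    return mask


def slice_focus_stats(grain_stack: GrainStack) -> pd.DataFrame:
    """Per-slice (min, max, contrast) within the dilated grain mask."""
    if grain_stack.n_slices < 1:
        raise ValueError("empty stack")
    mask = _stats_mask(grain_stack)
    records = []
    for i, sl in enumerate(grain_stack.voxels):
        vals = sl[mask]
        lo, hi = float(vals.min()), float(vals.max())
        records.append({"slice": i, "min": lo, "max": hi, "contrast": hi - lo})
    return pd.DataFrame(records)


def adaptive_focus_params(
    grain_stack: GrainStack,
    min_percentile: float = 25.0,
    max_percentile: float = 75.0,
    min_kept_slices: int = 3,
) -> FocusParams:
    """Place the thresholds at percentiles of the stack's own extrema."""
    stats = slice_focus_stats(grain_stack)
    lo = float(np.percentile(stats["min"], min_percentile))
    hi = float(np.percentile(stats["max"], max_percentile))
    return FocusParams(min_pixel_threshold=lo, max_pixel_threshold=hi, min_kept_slices=min_kept_slices)


def filter_slices(
    grain_stack: GrainStack,
    params: FocusParams | None = None,
) -> tuple[GrainStack, pd.DataFrame]:
    """Drop out-of-focus slices; never reorder or resample.

    Returns the filtered stack and a keep log (slice, min, max, kept).
    With ``params=None`` the dataset-adaptive percentile thresholds are
    used.  If fewer than ``min_kept_slices`` slices survive, the slices
    with the highest contrast are kept instead (original order) and a
    warning is logged.
    """
    if grain_stack.n_slices < 1:
        raise ValueError("empty stack")
    if params is None:
        params = adaptive_focus_params(grain_stack)
    stats = slice_focus_stats(grain_stack)
    keep = (stats["min"] <= params.min_pixel_threshold) & (
        stats["max"] >= params.max_pixel_threshold
    )
    if int(keep.sum()) < params.min_kept_slices:
        n = min(params.min_kept_slices, grain_stack.n_slices)
        best = stats.nlargest(n, "contrast", keep="first").index
        keep = stats.index.isin(best)
        keep = pd.Series(keep, index=stats.index)
        log.warning(
            "filter_slices: fewer than %d slices passed thresholds; keeping the %d "
            "highest-contrast slices instead",
            params.min_kept_slices,
            n,
        )
    kept_idx = stats.loc[keep, "slice"].to_numpy()
    stats = stats.assign(kept=keep.to_numpy())
    filtered = dc_replace(grain_stack, voxels=grain_stack.voxels[kept_idx])
    return filtered, stats
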