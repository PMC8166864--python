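"""End-to-end helpers: stack in, framed classifier inputs out.

These functions chain the pipeline stages (detect grains, crop, drop
out-of-focus slices, project, frame) and carry the per-grain logs the
individual stages produce, so callers — the command line, tests and
reproduction scripts — all run the identical path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionParams, detect_grains, extract_substack
from .focus import FocusParams, filter_slices
from .projections import project_grain
from .stack_io import DatasetManifest, FramedImage, ZStack, read_stack

log = logging.getLogger(__name__)


@dataclass
class StackResult:
    """Everything the projection stage produced for one stack."""

    frames: list[FramedImage]
    rejections: pd.DataFrame
    slice_logs: list[pd.DataFrame]


def process_stack(
    stack: ZStack,
    detection_params: DetectionParams | None = None,
    focus_params: FocusParams | None = None,
    margin_px: int = 8,
) -> StackResult:
    """Detect, crop, focus-filter and frame every grain in one stack."""
    result = detect_grains(stack, detection_params)
    frames: list[FramedImage] = []
    slice_logs: list[pd.DataFrame] = []
    for i, region in enumerate(result.regions):
        grain = extract_substack(stack, region, margin_px=margin_px)
        filtered, slice_log = filter_slices(grain, focus_params)
        if filtered.n_slices < 2:  # stddev projection needs >= 2 slices
            filtered, slice_log = filter_slices(
                grain,
                FocusParams(
                    min_pixel_threshold=float("inf"),
                    max_pixel_threshold=float("inf"),
                    min_kept_slices=2,
                ),
            )
        frame = project_grain(filtered)
        frame.provenance["region_index"] = i
        frames.append(frame)
        slice_logs.append(slice_log)
    return StackResult(frames=frames, rejections=result.rejections, slice_logs=slice_logs)


def frames_from_manifest(
    manifest: DatasetManifest,
    detection_params: DetectionParams | None = None,
    focus_params: FocusParams | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Project every manifest stack; returns (frames, labels, sample ids).

    Stacks where detection finds no usable grain are skipped with a
    warning (the manifest label applies to the whole single-grain stack,
    so multi-grain stacks contribute one frame per detected grain).
    """
    frames, labels, groups = [], [], []
    for _, row in manifest.records.iterrows():
        stack = read_stack(row["path"])
        result = process_stack(stack, detection_params, focus_params)
        if not result.frames:
            log.warning("no grain detected in %s; skipped", row["path"])
            continue
        for frame in result.frames:
            frame.provenance["source"] = str(row["path"])
            frames.append(frame.pixels)
            labels.append(row["label"])
            groups.append(row["sample_id"])
    if not frames:
        return np.empty((0, 276, 276, 3), dtype=np.float32), [], []
    return np.stack(frames), labels, groups


def project_folder(
    input_dir: str | Path,
    output_dir: str | Path,
    detection_params: DetectionParams | None = None,
    focus_params: FocusParams | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> pd.DataFrame:
    """Project every TIFF stack in a folder to framed images on disk.

    Returns an index table (source stack, frame path, n kept slices).
    Rejection and slice-keep logs are written next to the frames.
    """
    from .stack_io import write_framed_image

    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    records = []
    all_rejections = []
    stack_paths = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in (".tif", ".tiff")
    )
    for path in stack_paths:
        stack = read_stack(path, pixel_size_um=pixel_size_um, z_step_um=z_step_um)
        result = process_stack(stack, detection_params, focus_params)
        rej = result.rejections.assign(stack=str(path))
        all_rejections.append(rej)
        for i, frame in enumerate(result.frames):
            frame.provenance["source"] = str(path)
            out_path = output_dir / f"{path.stem}_grain{i:02d}.tif"
            write_framed_image(frame, out_path)
            result.slice_logs[i].to_csv(
                output_dir / f"{path.stem}_grain{i:02d}_slices.csv", index=False
            )
            records.append(
                {
                    "stack": str(path),
                    "frame": str(out_path),
                    "kept_slices": int(result.slice_logs[i]["kept"].sum()),
                }
            )
    index = pd.DataFrame(records, columns=["stack", "frame", "kept_slices"])
    index.to_csv(output_dir / "frames_index.csv", index=False)
    if all_rejections:
        pd.concat(all_rejections, ignore_index=True).to_csv(
            output_dir / "rejections.csv", index=False
        )
    return index
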