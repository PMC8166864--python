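"""Reading and writing calibrated Z-stacks, framed images and manifests.

Conventions used throughout the package:

* arrays are indexed ``(slice, row, col)``; slice 0 is the first acquired
  focal plane, coordinates are 0-based;
* intensities are stored unchanged — any rescaling (e.g. normalisation
  before framing) is explicit and recorded in provenance metadata;
* physical calibration (µm per pixel, µm per Z-step) travels with every
  stack.  TIFF resolution tags are written when possible, but a JSON
  sidecar (``<file>.json``) is the source of truth because TIFF tag
  dialects vary between writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

#: channel order of every framed classifier input
CHANNEL_ROLES = ("stddev", "min_intensity", "extended_focus")

#: side length of the fixed classifier input frame, in pixels
FRAME_PX = 276


class CalibrationError(ValueError):
    """Raised when a stack is read without any physical calibration."""


class PageShapeError(ValueError):
    """Raised when the pages of a multi-page TIFF disagree in shape."""


@dataclass
class ZStack:
    """A calibrated 3-D grayscale image (slices x rows x cols).

    Parameters
    ----------
    voxels
        Intensity array of shape ``(n_slices, rows, cols)``.  8-bit,
        16-bit and floating point data are supported; intensities are
        never rescaled implicitly.
    pixel_size_um
        Lateral calibration in micrometres per pixel.
    z_step_um
        Axial distance between consecutive slices in micrometres.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (slices, rows, cols); got shape {self.voxels.shape}")
        if self.voxels.shape[0] < 1:
            raise ValueError("a stack needs at least one slice")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.z_step_um > 0:
            raise ValueError("z_step_um must be positive")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def bit_depth(self) -> str:
        """One of ``"8"``, ``"16"`` or ``"float"``."""
        dt = self.voxels.dtype
        if dt == np.uint8:
            return "8"
        if dt == np.uint16:
            return "16"
        return "float"

    def slice_z_um(self, index: int) -> float:
        """Axial position of a slice relative to the first plane."""
        return index * self.z_step_um


@dataclass
class FramedImage:
    """The fixed-size, three-channel classifier input.

    ``pixels`` has shape ``(276, 276, 3)``; the channels hold the
    standard-deviation, minimum-intensity and extended-focus projections
    of one grain's focus-filtered sub-stack, each min–max normalised.
    The grain is placed unscaled with its centroid at the frame centre,
    so physical size information is preserved (``pixel_size_um`` is
    unchanged from the source stack).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_roles: tuple[str, str, str] = CHANNEL_ROLES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (FRAME_PX, FRAME_PX, 3):
            raise ValueError(
                f"framed image must be {FRAME_PX}x{FRAME_PX}x3; got {self.pixels.shape}"
            )
        if tuple(self.channel_roles) != CHANNEL_ROLES:
            raise ValueError(f"channel roles must be {CHANNEL_ROLES}")


# ---------------------------------------------------------------------------
# sidecar helpers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # TIFF resolution tags use pixels per unit; RESUNIT 3 = centimetre.
    px_per_cm = 1e4 / stack.pixel_size_um
    tifffile.imwrite(
        path,
        stack.voxels,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )
    _write_sidecar(
        path,
        {
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "n_slices": stack.n_slices,
            "bit_depth": stack.bit_depth,
        },
    )
    return path


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ZStack:
    """Read a multi-page TIFF into a :class:`ZStack`.

    Calibration is taken from explicit overrides first, then from the JSON
    sidecar.  A stack without any calibration raises
    :class:`CalibrationError` — the pipeline never invents a default scale.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = [page.shape for page in tif.pages]
        first = shapes[0]
        for i, shp in enumerate(shapes):
            if shp != first:
                raise PageShapeError(
                    f"{path}: page {i} has shape {shp}, expected {first} (page 0)"
                )
        voxels = tif.asarray()
    if voxels.ndim == 2:
        voxels = voxels[np.newaxis]
    sidecar = _read_sidecar(path)
    px = pixel_size_um if pixel_size_um is not None else sidecar.get("pixel_size_um")
    zs = z_step_um if z_step_um is not None else sidecar.get("z_step_um")
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel size found in sidecar and no override supplied"
        )
    if zs is None:
        raise CalibrationError(
            f"{path}: no Z-step found in sidecar and no override supplied"
        )
    return ZStack(voxels=voxels, pixel_size_um=float(px), z_step_um=float(zs))


# ---------------------------------------------------------------------------
# framed images
# ---------------------------------------------------------------------------

def write_framed_image(image: FramedImage, path: str | Path) -> Path:
    """Write a framed image losslessly (3-channel float TIFF + sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.asarray(image.pixels, dtype=np.float32)
    tifffile.imwrite(path, pixels, photometric="minisblack")
    _write_sidecar(
        path,
        {
            "channel_roles": list(image.channel_roles),
            "pixel_size_um": image.pixel_size_um,
            "provenance": image.provenance,
        },
    )
    return path


def read_framed_image(path: str | Path) -> FramedImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = _read_sidecar(path)
    roles = tuple(sidecar.get("channel_roles", CHANNEL_ROLES))
    if "pixel_size_um" not in sidecar:
        raise CalibrationError(f"{path}: framed-image sidecar lacks pixel_size_um")
    return FramedImage(
        pixels=pixels,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        channel_roles=roles,  # type: ignore[arg-type]
        provenance=sidecar.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("path", "label", "sample_id")


@dataclass
class DatasetManifest:
    """Table of (stack path, class label, sample/plant identifier).

    The sample identifier groups images of grains that came from the same
    plant or aerobiological sample, which lets cross-validation avoid
    leaking near-duplicate grains across folds.
    """

    records: pd.DataFrame
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        df = self.records
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if df["path"].duplicated().any():
            dup = df.loc[df["path"].duplicated(), "path"].iloc[0]
            raise ValueError(f"duplicate manifest path: {dup}")
        allowed = set(self.label_set) | {"unlabelled"}
        bad = set(df["label"]) - allowed
        if bad:
            raise ValueError(f"labels outside declared label set: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def paths(self) -> list[Path]:
        return [Path(p) for p in self.records["path"]]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.records.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)
    _write_sidecar(path, {"label_set": list(manifest.label_set)})
    return path


def read_manifest(path: str | Path, label_set: Sequence[str] | None = None) -> DatasetManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype={"path": str, "label": str, "sample_id": str})
    if label_set is None:
        sidecar = _read_sidecar(path)
        label_set = sidecar.get("label_set") or sorted(set(df["label"]) - {"unlabelled"})
    return DatasetManifest(records=df, label_set=tuple(label_set))
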