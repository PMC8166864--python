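"""Synthetic brightfield Z-stacks of Urticaceae-like pollen grains.

No public image set exists for the monitoring pipeline this package
implements, so every downstream stage is exercised on rendered phantoms
with known ground truth.  A phantom grain is a dark-rimmed disc (stained
grain on a bright background) with

* ``n_pores`` darker pore spots on the rim,
* a pore-adjacent rim thickening (the *annulus*) whose prominence is the
  main Urtica-vs-Parietaria contrast,
* multiplicative surface texture (scabrate ornamentation; coarser in
  Parietaria),
* a radial outline perturbation giving the slightly angular outline of
  many-pored grains (Urtica membranacea),
* per-slice Gaussian defocus whose width grows linearly with distance
  from the grain's sharpest focal plane, sigma(z) = sigma0 + k*|z - z_focus|.

The class presets encode only the *direction* of the morphological
contrasts reported for these taxa (sizes in micrometres, pore counts,
relative annulus/texture prominence); no quantitative ornamentation
measurements exist, so magnitudes are package choices, documented in the
methods note.

Rendering is fully deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .stack_io import DatasetManifest, ZStack, write_manifest, write_stack

CLASSES = ("urtica", "parietaria", "membranacea")

#: default lateral calibration, µm per pixel (100x oil objective class optics)
DEFAULT_PIXEL_SIZE_UM = 0.16
DEFAULT_N_SLICES = 20
DEFAULT_Z_STEP_UM = 1.8

#: defocus model sigma(z) = SIGMA0_PX + DEFOCUS_PX_PER_UM * |z - focal_z|
SIGMA0_PX = 0.8
DEFOCUS_PX_PER_UM = 0.9


@dataclass
class GrainPhantomParams:
    """Morphological parameters of one rendered grain."""

    class_label: str
    diameter_um: float
    n_pores: int
    annulus_strength: float  # in [0, 1]; rim thickening around pores
    texture_amplitude: float  # >= 0; multiplicative surface ornamentation
    outline_angularity: float  # in [0, 1]; radial outline perturbation
    focal_z_um: float  # axial position of the sharpest plane

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}; expected one of {CLASSES}")
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if self.n_pores < 1:
            raise ValueError("n_pores must be >= 1")
        if not 0.0 <= self.annulus_strength <= 1.0:
            raise ValueError("annulus_strength must be in [0, 1]")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        if not 0.0 <= self.outline_angularity <= 1.0:
            raise ValueError("outline_angularity must be in [0, 1]")


@dataclass
class ClassPreset:
    """Sampling ranges for one pollen class.

    ``diameter_um`` ranges follow the reported grain sizes (Urtica 13–20,
    Parietaria 11–16, U. membranacea 10–12 µm); pore counts 3–4 for the
    two genera versus >= 6 for U. membranacea.  Annulus prominence is
    high for Urtica and weak for Parietaria; texture is coarser for
    Parietaria; outline angularity is highest for the many-pored
    U. membranacea.
    """

    diameter_um: tuple[float, float]
    n_pores: tuple[int, int]
    annulus_strength: tuple[float, float]
    texture_amplitude: tuple[float, float]
    outline_angularity: tuple[float, float]

    def sample(self, rng: np.random.Generator, class_label: str, focal_z_um: float) -> GrainPhantomParams:
        return GrainPhantomParams(
            class_label=class_label,
            diameter_um=float(rng.uniform(*self.diameter_um)),
            n_pores=int(rng.integers(self.n_pores[0], self.n_pores[1] + 1)),
            annulus_strength=float(rng.uniform(*self.annulus_strength)),
            texture_amplitude=float(rng.uniform(*self.texture_amplitude)),
            outline_angularity=float(rng.uniform(*self.outline_angularity)),
            focal_z_um=focal_z_um,
        )


DEFAULT_PRESETS: dict[str, ClassPreset] = {
    "urtica": ClassPreset(
        diameter_um=(13.0, 20.0),
        n_pores=(3, 4),
        annulus_strength=(0.65, 0.95),
        texture_amplitude=(0.03, 0.10),
        outline_angularity=(0.05, 0.20),
    ),
    "parietaria": ClassPreset(
        diameter_um=(11.0, 16.0),
        n_pores=(3, 4),
        annulus_strength=(0.05, 0.30),
        texture_amplitude=(0.18, 0.35),
        outline_angularity=(0.05, 0.20),
    ),
    "membranacea": ClassPreset(
        diameter_um=(10.0, 12.0),
        n_pores=(6, 8),
        annulus_strength=(0.35, 0.60),
        texture_amplitude=(0.05, 0.15),
        outline_angularity=(0.45, 0.75),
    ),
}


@dataclass
class PlacedGrain:
    params: GrainPhantomParams
    center: tuple[float, float]  # (row, col) in pixels


@dataclass
class SceneConfig:
    """Full description of one rendered field of view."""

    image_shape_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_slices: int = DEFAULT_N_SLICES
    z_step_um: float = DEFAULT_Z_STEP_UM
    grains: list[PlacedGrain] = field(default_factory=list)
    debris_density: float = 0.0  # particles per 1000 µm²
    noise_sd: float = 0.0  # additive Gaussian noise, intensity units
    background_level: float = 200.0
    seed: int = 0

    @property
    def z_positions_um(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.z_step_um


@dataclass
class GrainRecord:
    """Ground truth for one grain in a scene."""

    center: tuple[float, float]
    diameter_um: float
    class_label: str
    overlaps: bool
    touches_border: bool


@dataclass
class GroundTruth:
    grains: list[GrainRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": g.center[0],
                    "col": g.center[1],
                    "diameter_um": g.diameter_um,
                    "label": g.class_label,
                    "overlaps": g.overlaps,
                    "touches_border": g.touches_border,
                }
                for g in self.grains
            ]
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grain_sharp_image(
    params: GrainPhantomParams,
    pixel_size_um: float,
    rng: np.random.Generator,
    half: int,
    background: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the in-focus appearance of one grain on a local canvas.

    Returns the sharp image (background included) and the boolean grain
    mask (pixels inside the perturbed outline).
    """
    # the soft edge plus residual focal-plane blur spreads the apparent
    # boundary outward by ~1.2 px; compensate so a thresholded mask of the
    # sharpest slice measures the nominal diameter
    radius_px = 0.5 * params.diameter_um / pixel_size_um - 1.2
    size = 2 * half + 1
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    rho = np.hypot(rr, cc)
    theta = np.arctan2(rr, cc)

    # outline: base circle + angular harmonic tied to the pore count
    phase = rng.uniform(0, 2 * np.pi)
    ell_phase = rng.uniform(0, 2 * np.pi)
    r_theta = radius_px * (
        1.0
        + 0.16 * params.outline_angularity * np.cos(params.n_pores * theta + phase)
        + 0.03 * np.cos(2 * theta + ell_phase)
    )

    edge_px = 0.5
    inside = 1.0 / (1.0 + np.exp(-(r_theta - rho) / edge_px))  # soft disc
    mask = rho <= r_theta

    # exine rim: dark ring just inside the outline
    rim_sigma = max(1.0, 0.45 / pixel_size_um * 0.5)  # ~0.45 µm wall
    rim_center = r_theta - 1.5 * rim_sigma
    rim = np.exp(-0.5 * ((rho - rim_center) / rim_sigma) ** 2)

    # pores: darker spots on the rim, evenly spaced with a small jitter
    pore_angles = (
        np.arange(params.n_pores) * 2 * np.pi / params.n_pores
        + phase
        + rng.normal(0, 0.08, params.n_pores)
    )
    pore_sigma = 0.9 / pixel_size_um * 0.5  # ~0.9 µm pore
    pores = np.zeros_like(rho)
    annulus = np.zeros_like(rho)
    for ang in pore_angles:
        pr = radius_px * (
            1.0
            + 0.16 * params.outline_angularity * np.cos(params.n_pores * ang + phase)
            + 0.03 * np.cos(2 * ang + ell_phase)
        ) - 1.2
        prow, pcol = pr * np.sin(ang), pr * np.cos(ang)
        d2 = (rr - prow) ** 2 + (cc - pcol) ** 2
        pores += np.exp(-0.5 * d2 / pore_sigma**2)
        # annulus: wider, shallower thickening around the pore
        annulus += np.exp(-0.5 * d2 / (2.2 * pore_sigma) ** 2)
    annulus *= rim  # thickening lives on the rim

    # multiplicative surface ornamentation inside the grain; scabrate
    # elements are ~0.8 µm, large enough to survive defocus
    speckle = rng.normal(0.0, 1.0, (size, size))
    speckle = ndimage.gaussian_filter(speckle, 0.8 / pixel_size_um * 0.5)
    speckle /= max(speckle.std(), 1e-9)

    depth = 0.55 * background
    darkness = inside * 0.45  # cytoplasm shading
    darkness += 0.75 * rim
    darkness += 0.55 * pores
    darkness += 0.85 * params.annulus_strength * annulus
    darkness *= 1.0 + params.texture_amplitude * speckle * inside
    darkness = np.clip(darkness, 0.0, 1.6)

    img = background - depth * darkness
    return np.clip(img, 1.0, None), mask


def _defocus_stack(
    sharp: np.ndarray,
    background: float,
    z_positions_um: Sequence[float],
    focal_z_um: float,
) -> np.ndarray:
    """Blur the sharp image per slice; blur width grows away from focus."""
    slices = []
    for z in z_positions_um:
        sigma = SIGMA0_PX + DEFOCUS_PX_PER_UM * abs(z - focal_z_um)
        slices.append(background + ndimage.gaussian_filter(sharp - background, sigma))
    return np.stack(slices)


def render_grain(
    params: GrainPhantomParams,
    optics: SceneConfig,
    rng: np.random.Generator | None = None,
) -> ZStack:
    """Render a single grain as a small Z-stack (no debris, no noise)."""
    radius_px = 0.5 * params.diameter_um / optics.pixel_size_um
    if 2 * radius_px < 4:
        raise ValueError(
            f"grain of {params.diameter_um} µm spans under 4 px at "
            f"{optics.pixel_size_um} µm/px; refusing to render"
        )
    if rng is None:
        rng = np.random.default_rng(optics.seed)
    max_sigma = SIGMA0_PX + DEFOCUS_PX_PER_UM * float(
        np.max(np.abs(optics.z_positions_um - params.focal_z_um))
    )
    half = int(np.ceil(radius_px + 3 * max_sigma + 4))
    sharp, _ = _grain_sharp_image(params, optics.pixel_size_um, rng, half, optics.background_level)
    voxels = _defocus_stack(sharp, optics.background_level, optics.z_positions_um, params.focal_z_um)
    return ZStack(
        voxels=voxels.astype(np.float32),
        pixel_size_um=optics.pixel_size_um,
        z_step_um=optics.z_step_um,
    )


def _render_debris(
    rng: np.random.Generator,
    config: SceneConfig,
) -> np.ndarray:
    """Dark irregular particles at random depths, composited over all slices."""
    rows, cols = config.image_shape_px
    area_um2 = rows * cols * config.pixel_size_um**2
    n = rng.poisson(config.debris_density * area_um2 / 1000.0)
    canvas = np.zeros((config.n_slices, rows, cols), dtype=np.float64)
    if n == 0:
        return canvas
    z_pos = config.z_positions_um
    for _ in range(n):
        cr, cc_ = rng.uniform(0, rows), rng.uniform(0, cols)
        # debris stays below the 5 µm grain-size cut even after defocus
        # spread, so the detector's size rule is its defence against it
        size_um = rng.uniform(1.0, 3.5)
        r_px = 0.5 * size_um / config.pixel_size_um
        n_vert = rng.integers(3, 8)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        radii = r_px * rng.uniform(0.5, 1.15, n_vert)
        vr = cr + radii * np.sin(angles)
        vc = cc_ + radii * np.cos(angles)
        sharp = np.zeros((rows, cols))
        pr, pc = draw_polygon(vr, vc, shape=(rows, cols))
        sharp[pr, pc] = rng.uniform(0.3, 0.7) * config.background_level
        focal = rng.uniform(z_pos[0], z_pos[-1]) if len(z_pos) > 1 else z_pos[0]
        for i, z in enumerate(z_pos):
            sigma = SIGMA0_PX + DEFOCUS_PX_PER_UM * abs(z - focal)
            canvas[i] -= ndimage.gaussian_filter(sharp, sigma)
    return canvas


def render_scene(config: SceneConfig) -> tuple[ZStack, GroundTruth]:
    """Composite all grains, debris and noise into one calibrated stack.

    Grains may legally overlap or cross the frame edge; such grains are
    flagged in the returned ground truth rather than rejected.
    """
    rows, cols = config.image_shape_px
    rng = np.random.default_rng(config.seed)
    canvas = np.full((config.n_slices, rows, cols), config.background_level, dtype=np.float64)

    masks: list[np.ndarray] = []
    for placed in config.grains:
        cr, cc_ = placed.center
        if not (0 <= cr < rows and 0 <= cc_ < cols):
            raise ValueError(f"grain centre {placed.center} outside image bounds {config.image_shape_px}")
        radius_px = 0.5 * placed.params.diameter_um / config.pixel_size_um
        max_sigma = SIGMA0_PX + DEFOCUS_PX_PER_UM * float(
            np.max(np.abs(config.z_positions_um - placed.params.focal_z_um))
        )
        half = int(np.ceil(radius_px + 3 * max_sigma + 4))
        sharp, gmask = _grain_sharp_image(
            placed.params, config.pixel_size_um, rng, half, config.background_level
        )
        sub = _defocus_stack(
            sharp, config.background_level, config.z_positions_um, placed.params.focal_z_um
        )
        ir, ic = int(round(cr)), int(round(cc_))
        r0, r1 = ir - half, ir + half + 1
        c0, c1 = ic - half, ic + half + 1
        sr0, sc0 = max(0, -r0), max(0, -c0)
        tr0, tc0 = max(0, r0), max(0, c0)
        tr1, tc1 = min(rows, r1), min(cols, c1)
        canvas[:, tr0:tr1, tc0:tc1] += (
            sub[:, sr0 : sr0 + (tr1 - tr0), sc0 : sc0 + (tc1 - tc0)]
            - config.background_level
        )
        full_mask = np.zeros((rows, cols), dtype=bool)
        full_mask[tr0:tr1, tc0:tc1] = gmask[sr0 : sr0 + (tr1 - tr0), sc0 : sc0 + (tc1 - tc0)]
        masks.append(full_mask)

    canvas += _render_debris(rng, config)
    if config.noise_sd > 0:
        canvas += rng.normal(0.0, config.noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, None)

    records = []
    dilated = [ndimage.binary_dilation(m) for m in masks]
    for i, placed in enumerate(config.grains):
        overlaps = any(
            j != i and np.any(dilated[i] & dilated[j]) for j in range(len(masks))
        )
        rim = np.zeros_like(masks[i])
        rim[0, :] = rim[-1, :] = rim[:, 0] = rim[:, -1] = True
        touches = bool(np.any(masks[i] & rim))
        records.append(
            GrainRecord(
                center=placed.center,
                diameter_um=placed.params.diameter_um,
                class_label=placed.params.class_label,
                overlaps=overlaps,
                touches_border=touches,
            )
        )
    stack = ZStack(
        voxels=canvas.astype(np.float32),
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
    )
    return stack, GroundTruth(grains=records)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def sample_grain(
    class_label: str,
    rng: np.random.Generator,
    presets: dict[str, ClassPreset] | None = None,
    n_slices: int = DEFAULT_N_SLICES,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    diameter_shift_um: float = 0.0,
    texture_scale: float = 1.0,
) -> GrainPhantomParams:
    """Draw one grain's parameters from a class preset.

    ``diameter_shift_um`` and ``texture_scale`` model mild plant-to-plant
    variability within a species.
    """
    presets = presets or DEFAULT_PRESETS
    z_mid = 0.5 * (n_slices - 1) * z_step_um
    focal = float(rng.uniform(z_mid - 2.5, z_mid + 2.5))
    p = presets[class_label].sample(rng, class_label, focal)
    lo, hi = presets[class_label].diameter_um
    d = float(np.clip(p.diameter_um + diameter_shift_um, lo * 0.95, hi * 1.05))
    return replace(
        p,
        diameter_um=d,
        texture_amplitude=float(p.texture_amplitude * texture_scale),
    )


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    class_presets: dict[str, ClassPreset] | None = None,
    seed: int = 0,
    n_plants: int = 4,
    image_shape_px: tuple[int, int] = (208, 208),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 3.0,
    debris_density: float = 0.02,
) -> DatasetManifest:
    """Write ``n_per_class`` single-grain stacks per class plus a manifest.

    Each grain is attributed to one of ``n_plants`` source plants per
    class; plants carry a small systematic diameter/texture offset so
    that grouped cross-validation has real structure to respect.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    presets = class_presets or DEFAULT_PRESETS
    master = np.random.default_rng(seed)
    rows = []
    for label in CLASSES:
        plant_rng = np.random.default_rng(master.integers(2**31))
        plant_shift = plant_rng.normal(0.0, 0.25, n_plants)
        plant_texture = plant_rng.lognormal(0.0, 0.08, n_plants)
        for i in range(n_per_class):
            plant = i % n_plants
            grain_rng = np.random.default_rng(master.integers(2**31))
            params = sample_grain(
                label,
                grain_rng,
                presets,
                diameter_shift_um=float(plant_shift[plant]),
                texture_scale=float(plant_texture[plant]),
            )
            config = SceneConfig(
                image_shape_px=image_shape_px,
                pixel_size_um=pixel_size_um,
                grains=[
                    PlacedGrain(
                        params=params,
                        center=(image_shape_px[0] / 2, image_shape_px[1] / 2),
                    )
                ],
                noise_sd=noise_sd,
                debris_density=debris_density,
                seed=int(grain_rng.integers(2**31)),
            )
            stack, _ = render_scene(config)
            path = out_dir / f"{label}_{i:04d}.tif"
            write_stack(stack, path)
            rows.append(
                {"path": str(path), "label": label, "sample_id": f"{label}_plant{plant}"}
            )
    manifest = DatasetManifest(records=pd.DataFrame(rows), label_set=CLASSES)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
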