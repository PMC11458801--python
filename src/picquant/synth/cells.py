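"""Synthetic multichannel cell scenes with planted ground truth.

A scene contains a cell (elliptical), its nucleus with bright nucleoli,
cytoplasm, optional stress granules and rod-shaped aggregate objects
planted to cover a requested fraction of the cytoplasm.  Three emission
channels are rendered (500-520, 565-585 and 600-620 nm); intensities are
12-bit integers and every generated dataset is accompanied by the exact
compartment masks and a ground-truth class map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..classify import (
    AGGREGATE,
    AGGREGATE_BAND,
    BACKGROUND,
    GRANULE_BAND,
    MONOMER,
    MONOMER_BAND,
    ClassifierParams,
    RoiSet,
    SpectralImage,
)
from ..errors import ParameterError, SizingError

FULL_SCALE = 4095
_MIN_SHAPE = 64


@dataclass(frozen=True)
class CellScene:
    """Parameters of one synthetic cell image."""

    image_shape: tuple[int, int] = (256, 256)
    monomer_level: float = 250.0  # mean cytosolic monomer intensity, counts
    monomer_spread: float = 0.0  # additional Gaussian SD on the monomer level
    planted_aggregate_fraction: float = 0.0
    aggregate_peak: float = 1200.0  # rod intensity in the 565-585 nm channel
    rod_length_px: int = 15
    rod_width_px: int = 3
    n_nucleoli: int = 2
    nucleolus_level: float = 900.0  # bright monomer staining inside the nucleus
    n_granules: int = 0
    granule_radius_px: int = 6
    granule_enrichment: float = 2.0  # monomer-channel granule/cytoplasm ratio
    noise: str = "none"  # "none" or "poisson-gaussian"
    gaussian_sd: float = 4.0
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_aggregate_fraction <= 1.0):
            raise ParameterError("planted_aggregate_fraction must lie in [0, 1]")
        if min(self.image_shape) < _MIN_SHAPE:
            raise SizingError(
                f"image {self.image_shape} too small; need at least "
                f"{_MIN_SHAPE} px per side for the compartments"
            )
        if self.noise not in ("none", "poisson-gaussian"):
            raise ParameterError("noise must be 'none' or 'poisson-gaussian'")
        if not (0 < self.monomer_level <= FULL_SCALE):
            raise ParameterError("monomer_level must lie in (0, 4095]")


@dataclass
class GeneratedScene:
    """Generator output: image, compartment masks and ground truth."""

    image: SpectralImage
    rois: RoiSet
    truth_classmap: np.ndarray
    planted_fraction: float  # realized aggregate coverage of the cytoplasm
    scene: CellScene = field(repr=False, default=None)


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rod_mask(shape, center, angle, length, width) -> np.ndarray:
    """Pixels within width/2 of a length-long segment through center."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d_r = rr - center[0]
    d_c = cc - center[1]
    u_r, u_c = np.sin(angle), np.cos(angle)
    along = d_r * u_r + d_c * u_c
    across = -d_r * u_c + d_c * u_r
    return (np.abs(along) <= length / 2.0) & (np.abs(across) <= width / 2.0)


def _build_compartments(scene: CellScene, rng: np.random.Generator) -> RoiSet:
    shape = scene.image_shape
    center = (shape[0] / 2.0, shape[1] / 2.0)
    cell_radii = (shape[0] * 0.42, shape[1] * 0.42)
    nucleus_radii = (shape[0] * 0.16, shape[1] * 0.16)
    cell = _ellipse_mask(shape, center, cell_radii)
    nucleus = _ellipse_mask(shape, center, nucleus_radii)

    nucleoli = np.zeros(shape, dtype=bool)
    nucleolus_r = max(2, int(min(shape) * 0.03))
    for _ in range(scene.n_nucleoli):
        for _attempt in range(200):
            dr = rng.uniform(-0.6, 0.6) * nucleus_radii[0]
            dc = rng.uniform(-0.6, 0.6) * nucleus_radii[1]
            disc = _disc_mask(shape, (center[0] + dr, center[1] + dc), nucleolus_r)
            if np.all(nucleus[disc]):  # nucleoli must lie within the nucleus
                nucleoli |= disc
                break

    cytoplasm = cell & ~nucleus
    granules = np.zeros(shape, dtype=bool)
    for _ in range(scene.n_granules):
        for _attempt in range(500):
            dr = rng.uniform(-0.9, 0.9) * cell_radii[0]
            dc = rng.uniform(-0.9, 0.9) * cell_radii[1]
            disc = _disc_mask(
                shape, (center[0] + dr, center[1] + dc), scene.granule_radius_px
            )
            if disc.any() and np.all(cytoplasm[disc]) and not (granules & disc).any():
                granules |= disc
                break

    # ten small background reference spots outside the cell
    spots = np.zeros(shape, dtype=bool)
    margin = 4
    n_spots = 0
    while n_spots < 10:
        r = rng.integers(margin, shape[0] - margin)
        c = rng.integers(margin, shape[1] - margin)
        disc = _disc_mask(shape, (r, c), 2)
        if not (cell[disc].any() or spots[disc].any()):
            spots |= disc
            n_spots += 1

    return RoiSet(
        {
            "cell": cell,
            "nucleus": nucleus,
            "nucleoli": nucleoli,
            "cytoplasm": cytoplasm,
            "granules": granules,
            "background_spots": spots,
        }
    )


def _plant_rods(
    scene: CellScene, cytoplasm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Plant rods until the covered cytoplasm fraction reaches the target."""
    target = int(round(scene.planted_aggregate_fraction * cytoplasm.sum()))
    planted = np.zeros(scene.image_shape, dtype=bool)
    if target == 0:
        return planted
    count = 0
    attempts = 0
    candidates = np.argwhere(cytoplasm)
    while count < target and attempts < 50000:
        attempts += 1
        r, c = candidates[rng.integers(len(candidates))]
        rod = _rod_mask(
            scene.image_shape,
            (float(r), float(c)),
            rng.uniform(0.0, np.pi),
            scene.rod_length_px,
            scene.rod_width_px,
        )
        rod &= cytoplasm  # clip to the compartment the rods live in
        new = rod & ~planted
        if new.any():
            planted |= new
            count = int(planted.sum())
    if count < target:
        raise ParameterError(
            "could not reach the requested aggregate fraction; cytoplasm too full"
        )
    return planted


def generate_cell_image(scene: CellScene) -> GeneratedScene:
    """Render a scene into channels + masks + ground-truth class map."""
    rng = np.random.default_rng(scene.seed)
    rois = _build_compartments(scene, rng)
    cell = rois.masks["cell"]
    nucleus = rois.masks["nucleus"]
    nucleoli = rois.masks["nucleoli"]
    cytoplasm = rois.masks["cytoplasm"]
    granules = rois.masks["granules"]
    rods = _plant_rods(scene, cytoplasm, rng)

    shape = scene.image_shape
    ch_granule = np.zeros(shape)  # 500-520 nm (protein marker)
    ch_aggregate = np.zeros(shape)  # 565-585 nm
    ch_monomer = np.zeros(shape)  # 600-620 nm

    ch_granule[cell] = 150.0
    ch_granule[nucleus] = 600.0
    ch_granule[granules] = 1500.0

    level = scene.monomer_level
    if scene.monomer_spread > 0:
        cellwise = level + rng.normal(0.0, scene.monomer_spread, size=shape)
    else:
        cellwise = np.full(shape, level)
    ch_aggregate[cell] = cellwise[cell]
    ch_aggregate[nucleoli] = scene.nucleolus_level
    ch_aggregate[rods] = scene.aggregate_peak

    ch_monomer[cell] = cellwise[cell]
    ch_monomer[nucleoli] = scene.nucleolus_level
    ch_monomer[granules] = level * scene.granule_enrichment

    channels = np.stack([ch_granule, ch_aggregate, ch_monomer])
    if scene.noise == "poisson-gaussian":
        channels = rng.poisson(np.clip(channels, 0, None)).astype(float)
        channels += rng.normal(0.0, scene.gaussian_sd, size=channels.shape)
    channels = np.clip(np.rint(channels), 0, FULL_SCALE).astype(np.uint16)

    image = SpectralImage(
        channels=channels,
        bands_nm=(GRANULE_BAND, AGGREGATE_BAND, MONOMER_BAND),
        full_scale=FULL_SCALE,
        pixel_size_um=scene.pixel_size_um,
    )

    truth = np.full(shape, BACKGROUND, dtype=np.uint8)
    truth[cell] = MONOMER
    truth[rods] = AGGREGATE
    realized = float(rods.sum() / cytoplasm.sum())
    return GeneratedScene(
        image=image,
        rois=rois,
        truth_classmap=truth,
        planted_fraction=realized,
        scene=scene,
    )


def default_classifier_params() -> ClassifierParams:
    """Classifier parameters matching the generator's intensity design."""
    return ClassifierParams()
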