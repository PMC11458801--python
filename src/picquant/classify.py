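"""Spectral classification of J-aggregate vs monomer signal.

Pixels of a multichannel image are labelled aggregate / monomer /
background from the intensity in the 565-585 nm (aggregate) channel using
a calibrated threshold; bright nucleolar regions are masked out first so
intense monomer staining in the nucleus is not miscounted.  Emission
spectra are classified from the band-intensity ratio plus the presence of
a sharp local peak near 575 nm, which also drives the threshold
calibration scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from .errors import (
    CalibrationError,
    ConfigurationError,
    ParameterError,
    ResolutionError,
)

# ClassMap label values
BACKGROUND = 0
MONOMER = 1
AGGREGATE = 2

AGGREGATE_BAND = (565.0, 585.0)
MONOMER_BAND = (600.0, 620.0)
GRANULE_BAND = (500.0, 520.0)


@dataclass
class SpectralImage:
    """Multichannel 2-D raster with emission-band metadata."""

    channels: np.ndarray  # (n_channels, H, W)
    bands_nm: tuple[tuple[float, float], ...]
    full_scale: int = 4095
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ParameterError("channels must be a (n_channels, H, W) array")
        if len(self.bands_nm) != self.channels.shape[0]:
            raise ParameterError("one emission band required per channel")
        if self.channels.min() < 0 or self.channels.max() > self.full_scale:
            raise ParameterError("intensities must lie in [0, full_scale]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, wavelength_nm: float) -> np.ndarray:
        """Channel whose emission band contains ``wavelength_nm``."""
        for img, (lo, hi) in zip(self.channels, self.bands_nm):
            if lo <= wavelength_nm <= hi:
                return img
        raise ConfigurationError(
            f"no channel covers {wavelength_nm} nm (bands: {self.bands_nm})"
        )


@dataclass
class RoiSet:
    """Named boolean compartment masks sharing one image shape."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, name: str, shape: tuple[int, int] | None = None) -> np.ndarray:
        if name in self.masks:
            return self.masks[name]
        if shape is None:
            raise KeyError(name)
        return np.zeros(shape, dtype=bool)

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass(frozen=True)
class ClassifierParams:
    """Intensity windows of the pixel classifier (12-bit counts)."""

    aggregate_threshold: float = 400.0
    monomer_window: tuple[float, float] = (175.0, 350.0)
    full_scale: int = 4095

    def __post_init__(self) -> None:
        lo, hi = self.monomer_window
        if not (0 < hi < self.aggregate_threshold <= self.full_scale):
            raise ParameterError(
                "require 0 < monomer_window.max < aggregate_threshold <= full_scale"
            )
        if lo >= hi:
            raise ParameterError("monomer window must be a proper interval")

    @property
    def background_floor(self) -> float:
        # pixels below one third of the monomer window minimum are background
        return self.monomer_window[0] / 3.0


def classify_pixels(
    image: SpectralImage,
    params: ClassifierParams | None = None,
    exclusion: RoiSet | np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel label map from the aggregate-band channel.

    A pixel is aggregate iff its 565-585 nm intensity is at or above the
    threshold (inclusive) and the pixel is not excluded; monomer iff it is
    below the threshold but above the background floor; everything else
    (including excluded nucleolar pixels) is background.
    """
    params = params or ClassifierParams()
    agg = np.asarray(image.channel(575.0), dtype=float)
    classmap = np.full(agg.shape, BACKGROUND, dtype=np.uint8)
    classmap[agg >= params.background_floor] = MONOMER
    classmap[agg >= params.aggregate_threshold] = AGGREGATE
    if exclusion is not None:
        if isinstance(exclusion, RoiSet):
            excl = exclusion.get("nucleoli", agg.shape)
        else:
            excl = np.asarray(exclusion, dtype=bool)
        classmap[excl] = BACKGROUND
    return classmap


def mask_nucleoli(
    image: SpectralImage,
    nucleus_mask: np.ndarray,
    min_contrast: float = 100.0,
) -> RoiSet:
    """Bright sub-regions inside the nucleus, flagged for exclusion.

    An Otsu cut restricted to the nucleus separates candidate bright
    regions; the split is only accepted when the bright/dark mean contrast
    exceeds ``min_contrast`` counts, so a uniform (noisy) nucleus yields an
    empty set.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    agg = np.asarray(image.channel(575.0), dtype=float)
    empty = RoiSet({"nucleoli": np.zeros(agg.shape, dtype=bool)})
    if not nucleus_mask.any():
        return empty
    values = agg[nucleus_mask]
    if np.ptp(values) == 0:
        return empty
    cut = threshold_otsu(values)
    bright = nucleus_mask & (agg > cut)
    dark = nucleus_mask & ~bright
    if not bright.any() or not dark.any():
        return empty
    if agg[bright].mean() - agg[dark].mean() < min_contrast:
        return empty
    return RoiSet({"nucleoli": bright})


def _band_mean(wavelength: np.ndarray, intensity: np.ndarray, band) -> float:
    lo, hi = band
    sel = (wavelength >= lo) & (wavelength <= hi)
    if not sel.any():
        raise ResolutionError(f"no samples in band {band}")
    return float(intensity[sel].mean())


def _noise_sd(wavelength: np.ndarray, intensity: np.ndarray) -> float:
    """High-frequency noise estimate from the red tail (>= 620 nm)."""
    sel = wavelength >= 620
    tail = intensity[sel] if sel.sum() >= 5 else intensity
    return float(np.diff(tail).std() / np.sqrt(2.0)) if tail.size > 2 else 0.0


def peak_sharpness(wavelength: np.ndarray, intensity: np.ndarray) -> float:
    """Prominence of a local maximum near 575 nm over its 570/580 shoulders.

    Returns 0 when the extremum in the 570-580 nm window sits on the window
    edge (no interior local maximum, as for the broad monomer band)."""
    win = (wavelength >= 570) & (wavelength <= 580)
    idx = np.flatnonzero(win)
    if idx.size < 3:
        raise ResolutionError("spectral grid too sparse around 575 nm")
    local = intensity[idx]
    p = int(np.argmax(local))
    if p == 0 or p == local.size - 1:
        return 0.0
    return float(local[p] - 0.5 * (local[0] + local[-1]))


def classify_spectrum(
    wavelength_nm: np.ndarray,
    intensity: np.ndarray,
    score_cutoff: float = 1.5,
    prominence_factor: float = 3.0,
    min_prominence: float = 0.0,
) -> tuple[str, float]:
    """Label a spectrum aggregate/monomer; returns (label, band score).

    score = mean(565-585) / mean(600-620).  A spectrum is aggregate iff the
    score exceeds ``score_cutoff`` AND a sharp interior peak near 575 nm
    rises above ``prominence_factor`` times the estimated noise SD (with an
    absolute floor ``min_prominence``).
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if wavelength_nm.min() > 540 or wavelength_nm.max() < 650:
        raise ParameterError("spectrum must cover at least 540-650 nm")
    if np.max(np.diff(wavelength_nm)) > 5.0:
        raise ResolutionError("wavelength spacing above 5 nm")
    score = _band_mean(wavelength_nm, intensity, AGGREGATE_BAND) / max(
        _band_mean(wavelength_nm, intensity, MONOMER_BAND), 1e-12
    )
    prominence = peak_sharpness(wavelength_nm, intensity)
    floor = max(min_prominence, prominence_factor * _noise_sd(wavelength_nm, intensity))
    is_aggregate = score > score_cutoff and prominence > floor
    return ("aggregate" if is_aggregate else "monomer"), score


def calibrate_threshold(
    samples: list[tuple[float, np.ndarray, np.ndarray]],
    params: ClassifierParams | None = None,
    levels: np.ndarray | None = None,
    **spectrum_kwargs,
) -> float:
    """Lowest intensity level above which every pixel shows the sharp peak.

    ``samples`` are (aggregate-channel intensity, wavelength grid,
    spectrum) triples.  Candidate levels default to the observed unique
    intensities; the returned level is guaranteed to exceed the monomer
    window maximum.  Raises :class:`CalibrationError` when no level
    separates the classes.
    """
    params = params or ClassifierParams()
    if not samples:
        raise CalibrationError("no labelled samples supplied")
    intensities = np.array([s[0] for s in samples], dtype=float)
    labels = np.array(
        [classify_spectrum(wl, sp, **spectrum_kwargs)[0] for _, wl, sp in samples]
    )
    if levels is None:
        candidates = np.unique(intensities)
    else:
        candidates = np.unique(np.asarray(levels, dtype=float))
    for level in candidates:
        if level < params.monomer_window[1]:
            continue
        above = intensities >= level
        if above.any() and np.all(labels[above] == "aggregate") and level > params.monomer_window[1]:
            return float(level)
        # a level exactly at the monomer maximum is never acceptable
    raise CalibrationError("no intensity level separates aggregate from monomer")


def aggregate_area_fraction(
    classmap: np.ndarray, cytoplasm_mask: np.ndarray
) -> float:
    """Percent of cytoplasm pixels labelled aggregate."""
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if not cytoplasm_mask.any():
        raise ParameterError("cytoplasm mask is empty")
    n_agg = int(np.count_nonzero((classmap == AGGREGATE) & cytoplasm_mask))
    return 100.0 * n_agg / int(np.count_nonzero(cytoplasm_mask))


def area_fraction_summary(
    per_cell: list[tuple[np.ndarray, np.ndarray]],
) -> dict[str, float | list[float]]:
    """Per-cell aggregate area fractions plus mean +/- SD and a pooled-pixel
    variant (the paper-style average across cells is the headline number)."""
    fractions = [aggregate_area_fraction(cm, mask) for cm, mask in per_cell]
    n_agg = sum(
        int(np.count_nonzero((cm == AGGREGATE) & np.asarray(m, bool)))
        for cm, m in per_cell
    )
    n_cyto = sum(int(np.count_nonzero(m)) for _, m in per_cell)
    return {
        "per_cell_pct": fractions,
        "mean_pct": float(np.mean(fractions)),
        "sd_pct": float(np.std(fractions, ddof=1)) if len(fractions) > 1 else 0.0,
        "pooled_pct": 100.0 * n_agg / n_cyto,
        "n_cells": len(fractions),
    }


def colocalize_with_granules(
    classmap: np.ndarray,
    granule_mask: np.ndarray,
    monomer_channel: np.ndarray,
    cytoplasm_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-granule class content and monomer-channel enrichment ratio.

    The enrichment ratio compares mean 600-620 nm intensity inside each
    granule with the granule-free cytoplasm.  No granules yields an empty
    table (not an error).
    """
    granule_mask = np.asarray(granule_mask)
    labels = granule_mask if granule_mask.dtype != bool else _label(granule_mask)
    monomer_channel = np.asarray(monomer_channel, dtype=float)
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    cyto_free = cytoplasm_mask & (labels == 0)
    cyto_mean = monomer_channel[cyto_free].mean() if cyto_free.any() else np.nan
    rows = []
    for gid in np.unique(labels):
        if gid == 0:
            continue
        sel = labels == gid
        n_px = int(np.count_nonzero(sel))
        mean_monomer = float(monomer_channel[sel].mean())
        if not np.isfinite(cyto_mean) or cyto_mean <= 0:
            warnings.warn("no granule-free cytoplasm for enrichment", stacklevel=2)
            enrichment = np.nan
        else:
            enrichment = mean_monomer / cyto_mean
        rows.append(
            {
                "granule_id": int(gid),
                "n_px": n_px,
                "frac_aggregate": np.count_nonzero(classmap[sel] == AGGREGATE) / n_px,
                "frac_monomer": np.count_nonzero(classmap[sel] == MONOMER) / n_px,
                "frac_background": np.count_nonzero(classmap[sel] == BACKGROUND) / n_px,
                "mean_monomer_intensity": mean_monomer,
                "enrichment_ratio": enrichment,
            }
        )
    columns = [
        "granule_id", "n_px", "frac_aggregate", "frac_monomer",
        "frac_background", "mean_monomer_intensity", "enrichment_ratio",
    ]
    return pd.DataFrame(rows, columns=columns)
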