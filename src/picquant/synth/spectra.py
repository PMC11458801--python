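"""Synthetic emission spectra of the monomer and aggregate species.

The monomer is a weak broad band spanning roughly 520-650 nm with its
maximum at 560 nm; the aggregate is an intense narrow band at 575 nm.
Mixtures are convex combinations of the two pure models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian emission-band model of one species."""

    species: str  # "monomer" | "aggregate"
    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in ("monomer", "aggregate"):
            raise ParameterError("species must be 'monomer' or 'aggregate'")
        if self.width_nm <= 0 or self.amplitude < 0:
            raise ParameterError("width must be positive, amplitude non-negative")

    def evaluate(self, wavelength_nm: np.ndarray) -> np.ndarray:
        wavelength_nm = np.asarray(wavelength_nm, dtype=float)
        return self.baseline + self.amplitude * np.exp(
            -((wavelength_nm - self.center_nm) ** 2) / (2.0 * self.width_nm**2)
        )


def monomer_model(amplitude: float = 1.0) -> SpectrumModel:
    """Broad monomer band peaking at 560 nm."""
    return SpectrumModel("monomer", center_nm=560.0, width_nm=35.0, amplitude=amplitude)


def aggregate_model(amplitude: float = 10.0) -> SpectrumModel:
    """Sharp aggregate band at 575 nm (width << monomer width)."""
    return SpectrumModel("aggregate", center_nm=575.0, width_nm=3.0, amplitude=amplitude)


def generate_emission_spectrum(
    mixture_weight: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength_nm: np.ndarray | None = None,
    monomer: SpectrumModel | None = None,
    aggregate: SpectrumModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend of aggregate (weight w) and monomer (1 - w) emission.

    Returns ``(wavelength_nm, intensity)`` on a grid covering 500-700 nm
    (default 1 nm steps) with optional additive Gaussian noise.
    """
    if not (0.0 <= mixture_weight <= 1.0):
        raise ParameterError("mixture_weight must lie in [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if wavelength_nm is None:
        wavelength_nm = np.arange(500.0, 700.0 + 0.5, 1.0)
    else:
        wavelength_nm = np.asarray(wavelength_nm, dtype=float)
        if wavelength_nm.min() > 500 or wavelength_nm.max() < 700:
            raise ParameterError("wavelength grid must cover 500-700 nm")
    monomer = monomer or monomer_model()
    aggregate = aggregate or aggregate_model()
    intensity = (1.0 - mixture_weight) * monomer.evaluate(wavelength_nm)
    intensity = intensity + mixture_weight * aggregate.evaluate(wavelength_nm)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return wavelength_nm, intensity
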