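"""Synthetic temperature-ramp absorbance spectra.

Each spectrum spans 400-600 nm at 1 nm steps; the broad monomer
absorption band is always present and a narrow 573 nm aggregate peak
appears only at temperatures strictly below the planted threshold.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..errors import ParameterError
from ..uvvis import AbsorbanceRamp

WAVELENGTH_GRID_NM = np.arange(400.0, 600.0 + 0.5, 1.0)


def generate_absorbance_ramp(
    t_ja_true_c: float,
    temperatures_c: np.ndarray,
    peak_amplitude: float | Callable[[float], float] = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    monomer_amplitude: float = 1.0,
) -> AbsorbanceRamp:
    """Ramp with the sharp 573 nm peak planted strictly below ``t_ja_true_c``.

    A threshold above the grid start makes every spectrum carry the peak
    (downstream detection is start-censored); below the grid end no
    spectrum carries it (detection reports not reached).
    """
    temperatures_c = np.asarray(temperatures_c, dtype=float)
    if temperatures_c.size == 0:
        raise ParameterError("empty temperature grid")
    if np.any(np.diff(temperatures_c) >= 0):
        raise ParameterError("temperature grid must be strictly descending")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    wl = WAVELENGTH_GRID_NM
    monomer_band = monomer_amplitude * np.exp(-((wl - 522.0) ** 2) / (2.0 * 20.0**2))
    spectra = np.empty((temperatures_c.size, wl.size))
    for i, temp in enumerate(temperatures_c):
        spectrum = monomer_band + 0.02
        if temp < t_ja_true_c:
            amp = peak_amplitude(temp) if callable(peak_amplitude) else peak_amplitude
            spectrum = spectrum + amp * np.exp(-((wl - 573.0) ** 2) / (2.0 * 1.5**2))
        if noise_sd > 0:
            spectrum = spectrum + rng.normal(0.0, noise_sd, wl.size)
        spectra[i] = np.clip(spectrum, 0.0, None)
    return AbsorbanceRamp(
        temperatures_C=temperatures_c, wavelength_nm=wl, absorbance=spectra
    )
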