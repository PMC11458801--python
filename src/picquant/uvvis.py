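"""Aggregation-threshold-temperature detection from absorbance ramps.

On cooling, a sharp absorbance peak at 573 nm marks the onset of
J-aggregation.  The detector measures the prominence of that peak over a
linear baseline through 560 and 590 nm and reports the highest temperature
at which the peak is present and persists at every lower measured
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

PEAK_NM = 573.0
PEAK_WINDOW_NM = 2.0
BASELINE_LEFT_NM = 560.0
BASELINE_RIGHT_NM = 590.0


@dataclass
class AbsorbanceRamp:
    """Temperature-ramp absorbance spectra (descending temperatures)."""

    temperatures_C: np.ndarray  # strictly descending, (nT,)
    wavelength_nm: np.ndarray  # ascending, covers 573 nm, (nW,)
    absorbance: np.ndarray  # (nT, nW), non-negative

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.temperatures_C) >= 0):
            raise ParameterError("temperatures must be strictly descending")
        if not (self.wavelength_nm.min() <= PEAK_NM <= self.wavelength_nm.max()):
            raise ParameterError("wavelength grid must cover 573 nm")
        if self.absorbance.shape != (self.temperatures_C.size, self.wavelength_nm.size):
            raise ParameterError("absorbance must be (n_temperatures, n_wavelengths)")
        if self.absorbance.min() < -1e-9:
            raise ParameterError("absorbance must be non-negative")


@dataclass
class TjaResult:
    """Detected threshold temperature with censoring status.

    ``censored`` is 'none' for an interior detection, 'start' when the peak
    is already present in the first spectrum (true threshold at or above
    the ramp start) and 'not_reached' when no persistent peak appears.
    """

    T_JA_C: float | None
    censored: str

    @property
    def detected(self) -> bool:
        return self.T_JA_C is not None


def _nearest_index(grid: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(grid - value)))


def peak_prominence_573(
    wavelength_nm: np.ndarray, absorbance: np.ndarray
) -> float:
    """Prominence of the 573 +/- 2 nm maximum over a 560-590 nm baseline.

    The baseline is the straight line through the absorbances at 560 and
    590 nm; spectra without the sharp aggregate band sit at or below that
    chord in this window, so their prominence is ~0 or negative.
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    window = (wavelength_nm >= PEAK_NM - PEAK_WINDOW_NM) & (
        wavelength_nm <= PEAK_NM + PEAK_WINDOW_NM
    )
    if not window.any():
        raise ParameterError("no samples within 573 +/- 2 nm")
    i_left = _nearest_index(wavelength_nm, BASELINE_LEFT_NM)
    i_right = _nearest_index(wavelength_nm, BASELINE_RIGHT_NM)
    wl_l, wl_r = wavelength_nm[i_left], wavelength_nm[i_right]
    a_l, a_r = absorbance[i_left], absorbance[i_right]
    idx = np.flatnonzero(window)
    peak_i = idx[int(np.argmax(absorbance[idx]))]
    baseline = a_l + (a_r - a_l) * (wavelength_nm[peak_i] - wl_l) / (wl_r - wl_l)
    return float(absorbance[peak_i] - baseline)


def detect_peak_onset(
    ramp: AbsorbanceRamp,
    prominence_floor: float = 0.05,
    relative: bool = False,
) -> TjaResult:
    """Threshold temperature from the appearance of the sharp 573 nm peak.

    The peak must persist at every lower measured temperature, which
    guards against single-spectrum noise blips.  In ``relative`` mode the
    prominence is normalized by the spectrum maximum before comparison
    with the floor, making detection invariant to uniform scaling.
    """
    present = np.empty(ramp.temperatures_C.size, dtype=bool)
    for i in range(ramp.temperatures_C.size):
        prom = peak_prominence_573(ramp.wavelength_nm, ramp.absorbance[i])
        if relative:
            scale = ramp.absorbance[i].max()
            prom = prom / scale if scale > 0 else 0.0
        present[i] = prom > prominence_floor
    if not present.any():
        return TjaResult(T_JA_C=None, censored="not_reached")
    missing = np.flatnonzero(~present)
    if missing.size == 0:
        # sharp peak already in the first (warmest) spectrum: start-censored
        return TjaResult(T_JA_C=float(ramp.temperatures_C[0]), censored="start")
    onset = missing[-1] + 1
    if onset >= ramp.temperatures_C.size:
        return TjaResult(T_JA_C=None, censored="not_reached")
    return TjaResult(T_JA_C=float(ramp.temperatures_C[onset]), censored="none")


def threshold_vs_condition(
    ramps_by_condition: Mapping[str, Sequence[AbsorbanceRamp]],
    prominence_floor: float = 0.05,
    relative: bool = False,
) -> pd.DataFrame:
    """Mean detected threshold temperature per condition (replicates averaged).

    Conditions whose replicates are all censored are reported with a NaN
    mean and ``censored=True`` so they can be excluded from downstream
    comparisons rather than silently dropped.
    """
    rows = []
    for condition, ramps in ramps_by_condition.items():
        if len(ramps) == 0:
            raise ParameterError(f"condition {condition!r} has no ramps")
        results = [
            detect_peak_onset(r, prominence_floor=prominence_floor, relative=relative)
            for r in ramps
        ]
        detected = [r.T_JA_C for r in results if r.censored == "none"]
        rows.append(
            {
                "condition": condition,
                "n_replicates": len(ramps),
                "n_detected": len(detected),
                "T_JA_C": float(np.mean(detected)) if detected else np.nan,
                "censored": len(detected) == 0,
            }
        )
    return pd.DataFrame(rows)
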