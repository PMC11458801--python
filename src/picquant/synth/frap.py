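"""Synthetic FRAP traces following the single-exponential recovery model."""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from ..frap import FrapTrace


def recovery_curve(t_s: np.ndarray, i0: float, a: float, beta: float) -> np.ndarray:
    """I0 - a exp(-beta t) for t >= 0; pre-bleach plateau 1 for t < 0."""
    t_s = np.asarray(t_s, dtype=float)
    return np.where(t_s < 0, 1.0, i0 - a * np.exp(-beta * np.clip(t_s, 0, None)))


def generate_frap_trace(
    i0: float,
    a: float,
    beta: float,
    t_grid_s: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    normalized: bool = False,
    background_level: float = 50.0,
    reference_level: float = 1000.0,
    bleach_scale: float = 800.0,
) -> FrapTrace:
    """Synthesize a recovery trace with reference and background channels.

    ``normalized=True`` bypasses the raw-signal model and emits the
    normalized curve directly (for round-trip and fit testing); otherwise
    raw counts are built as background + scaled curve, with a constant
    reference channel so normalization can be tested exactly.
    """
    if not (0.0 <= i0 <= 1.0):
        raise ParameterError("I0 must lie in [0, 1]")
    if a < 0:
        raise ParameterError("amplitude a must be non-negative")
    if beta <= 0:
        raise ParameterError("beta must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    t_grid_s = np.asarray(t_grid_s, dtype=float)
    if t_grid_s.size == 0:
        raise ParameterError("empty time grid")

    rng = np.random.default_rng(seed)
    curve = recovery_curve(t_grid_s, i0, a, beta)
    if normalized:
        noisy = curve + (rng.normal(0.0, noise_sd, t_grid_s.shape) if noise_sd else 0.0)
        return FrapTrace(t_s=t_grid_s, bleached=noisy, normalized=noisy.copy())

    background = np.full(t_grid_s.shape, background_level)
    reference = np.full(t_grid_s.shape, background_level + reference_level)
    bleached = background_level + bleach_scale * curve
    if noise_sd > 0:
        scale = noise_sd * bleach_scale
        background = background + rng.normal(0.0, scale, t_grid_s.shape)
        reference = reference + rng.normal(0.0, scale, t_grid_s.shape)
        bleached = bleached + rng.normal(0.0, scale, t_grid_s.shape)
    return FrapTrace(
        t_s=t_grid_s, bleached=bleached, reference=reference, background=background
    )
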