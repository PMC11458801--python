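"""Synthetic time-resolved multi-angle SLS/DLS series for droplet growth.

A nucleation-and-growth model converts solute mass into spherical droplets
whose radius grows after the nucleation time.  Per frame, static
intensities follow the exact sphere form factor of the instantaneous
(lognormal) size distribution and the field correlation functions are
intensity-weighted sums of single exponentials with Stokes-Einstein
diffusion coefficients, so every downstream fit has a known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError
from ..scattering import (
    DEFAULT_ANGLES_DEG,
    N_AVOGADRO,
    ScatteringCalibration,
    ScatteringFrame,
    contrast_factor,
    diffusion_from_radius,
    momentum_transfer,
)


@dataclass(frozen=True)
class DropletGrowthModel:
    """Nucleation-and-growth ground truth for a scattering series."""

    nucleation_time_s: float
    final_radius_nm: float
    growth_tau_s: float  # time constant of the saturating radius growth
    baseline_Mw_g_mol: float
    baseline_Rh_nm: float = 3.0
    polydispersity: float = 0.0  # relative SD of the droplet radius (lognormal)
    droplet_density_g_ml: float = 1.1
    final_mass_fraction: float = 1.0  # solute mass fraction converted at r_final

    def __post_init__(self) -> None:
        if self.final_radius_nm <= 0 or self.growth_tau_s <= 0:
            raise ParameterError("radius and growth time constant must be positive")
        if not (0.0 <= self.polydispersity < 1.0):
            raise ParameterError("polydispersity must lie in [0, 1)")
        if not (0.0 < self.final_mass_fraction <= 1.0):
            raise ParameterError("final_mass_fraction must lie in (0, 1]")

    def radius_nm(self, t_s):
        """Median droplet radius; zero before nucleation, then monotone."""
        t_s = np.asarray(t_s, dtype=float)
        dt = np.clip(t_s - self.nucleation_time_s, 0.0, None)
        r = self.final_radius_nm * (1.0 - np.exp(-dt / self.growth_tau_s))
        return np.where(t_s < self.nucleation_time_s, 0.0, r)

    def sphere_mass_g_mol(self, radius_nm):
        """Molar mass of a droplet of the given radius."""
        r_cm = np.asarray(radius_nm, dtype=float) * 1e-7
        return (4.0 / 3.0) * np.pi * r_cm**3 * self.droplet_density_g_ml * N_AVOGADRO

    def number_density_per_ml(self, conc_g_l: float) -> float:
        """Constant post-nucleation droplet number density implied by the
        final mass fraction and final radius."""
        m_final = self.sphere_mass_g_mol(self.final_radius_nm)
        return self.final_mass_fraction * (conc_g_l * 1e-3) * N_AVOGADRO / m_final


def sphere_form_factor(q_nm, radius_nm):
    """Exact homogeneous-sphere form factor P(q)."""
    u = np.asarray(q_nm, dtype=float) * np.asarray(radius_nm, dtype=float)
    out = np.ones_like(u, dtype=float)
    nz = u > 1e-8
    un = u[nz]
    out[nz] = (3.0 * (np.sin(un) - un * np.cos(un)) / un**3) ** 2
    return out


def _radius_quadrature(median_nm: float, polydispersity: float, n_nodes: int = 15):
    """Lognormal radius distribution as (radii, number weights)."""
    if polydispersity <= 0:
        return np.array([median_nm]), np.array([1.0])
    sigma = np.sqrt(np.log(1.0 + polydispersity**2))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    radii = median_nm * np.exp(np.sqrt(2.0) * sigma * nodes)
    return radii, weights / np.sqrt(np.pi)


def _frame_population(
    model: DropletGrowthModel, calib: ScatteringCalibration, t_s: float
):
    """Species list (radius_nm, Rh_nm, molar mass, mass concentration g/cm3)."""
    c_total = calib.conc_g_l * 1e-3
    r_med = float(model.radius_nm(t_s))
    species_r = np.array([0.0])
    species_rh = np.array([model.baseline_Rh_nm])
    species_m = np.array([model.baseline_Mw_g_mol])
    species_c = np.array([c_total])
    if r_med > 0:
        radii, weights = _radius_quadrature(r_med, model.polydispersity)
        masses = model.sphere_mass_g_mol(radii)
        n_density = model.number_density_per_ml(calib.conc_g_l)
        mean_mass_g = float(np.sum(weights * masses)) / N_AVOGADRO
        phi = min(n_density * mean_mass_g / c_total, 1.0)
        mass_weights = weights * masses / np.sum(weights * masses)
        species_r = np.concatenate([species_r, radii])
        species_rh = np.concatenate([species_rh, radii])
        species_m = np.concatenate([species_m, masses])
        species_c = np.concatenate(
            [[(1.0 - phi) * c_total], phi * c_total * mass_weights]
        )
    return species_r, species_rh, species_m, species_c


def true_weight_average_mw(
    model: DropletGrowthModel, calib: ScatteringCalibration, t_s: float
) -> float:
    """Ground-truth Mw(t) = sum(c_i M_i) / sum(c_i)."""
    _, _, masses, concs = _frame_population(model, calib, t_s)
    return float(np.sum(concs * masses) / np.sum(concs))


def generate_scattering_series(
    model: DropletGrowthModel,
    calib: ScatteringCalibration,
    frame_interval_s: float = 10.0,
    n_frames: int = 40,
    pre_frames: int = 12,  # enough baseline frames for a stable 3-sigma level
    noise: float = 0.0,  # relative SD on excess scattering; additive 0.1x on g1
    seed: int = 0,
    angles_deg: np.ndarray | None = None,
    tau_s: np.ndarray | None = None,
    solvent_level: float = 0.05,
) -> list[ScatteringFrame]:
    """Emit a time-ordered list of frames with baseline (t < 0) frames first.

    Frame times are ``(i - pre_frames) * frame_interval_s``; negative times
    carry only the baseline solute, emulating the pre-addition record.
    """
    if noise < 0:
        raise ParameterError("noise must be non-negative")
    angles = DEFAULT_ANGLES_DEG if angles_deg is None else np.asarray(angles_deg, float)
    if angles.size != 8 or not np.allclose(np.diff(angles), 8.0):
        raise ParameterError("expected 8 detector angles at 8 degree increments")
    if tau_s is None:
        tau_s = np.logspace(-6, 0.5, 90)
    q_nm = momentum_transfer(angles, calib.n, calib.lambda0_nm)
    k_opt = contrast_factor(calib)
    rng = np.random.default_rng(seed)

    if q_nm.max() * np.sqrt(3.0 / 5.0) * model.final_radius_nm > 2.0:
        if np.all(q_nm * np.sqrt(3.0 / 5.0) * model.final_radius_nm > 2.0):
            warnings.warn(
                "q*Rg > 2 at every angle: Guinier regime violated", stacklevel=2
            )

    frames: list[ScatteringFrame] = []
    for i in range(pre_frames + n_frames):
        t = (i - pre_frames) * frame_interval_s
        radii, rhs, masses, concs = _frame_population(model, calib, t)
        # static: dR(q) = K * sum_i c_i M_i P_i(q)
        partial = concs[:, None] * masses[:, None] * sphere_form_factor(
            q_nm[None, :], radii[:, None]
        )
        d_r = k_opt * partial.sum(axis=0)
        # dynamic: intensity-weighted sum of single exponentials
        d_coefs = diffusion_from_radius(rhs, calib)  # m^2/s
        decay = np.exp(
            -((q_nm[None, :, None] * 1e9) ** 2)
            * d_coefs[:, None, None]
            * tau_s[None, None, :]
        )
        g1 = (partial[:, :, None] * decay).sum(axis=0) / partial.sum(axis=0)[:, None]

        if noise > 0:
            d_r = d_r * (1.0 + rng.normal(0.0, noise, d_r.shape))
            g1 = g1 + rng.normal(0.0, 0.1 * noise, g1.shape)
        g1 = np.clip(g1, None, 1.0)

        r_std = np.ones_like(q_nm)
        r_solv = np.full_like(q_nm, solvent_level)
        r_sol = r_solv + d_r / calib.rr_std * r_std
        frames.append(
            ScatteringFrame(
                t_s=t,
                angles_deg=angles,
                r_sol=r_sol,
                r_solv=r_solv,
                r_std=r_std,
                tau_s=tau_s,
                g1=g1,
            )
        )
    return frames


def siegert(g1: np.ndarray, coherence: float = 1.0) -> np.ndarray:
    """Siegert transform g2 = 1 + coherence * |g1|^2 (interface testing)."""
    return 1.0 + coherence * np.abs(np.asarray(g1, dtype=float)) ** 2
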