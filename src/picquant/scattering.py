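"""Time-resolved multi-angle SLS/DLS evaluation.

Static light scattering frames are reduced to the excess Rayleigh ratio,
fitted with the Zimm or Guinier linearization to obtain the weight-averaged
molar mass ``Mw`` and radius of gyration ``Rg``.  Dynamic data (field
correlation functions) are analysed with a second-order cumulant fit per
angle; the apparent diffusion coefficients are extrapolated to q^2 = 0,
converted to a hydrodynamic radius via Stokes-Einstein and combined into the
structure-sensitive ratio ``rho = Rg/Rh``.  ``analyze_series`` chains the
steps over a time series and detects the induction time of droplet growth.

Unit conventions
----------------
* scattering vector ``q``: 1/nm (wavelengths in nm)
* Rayleigh ratios: 1/cm
* concentration: g/l externally, converted to g/cm^3 internally
* contrast factor ``K``: cm^2 mol / g^2, so that K*c/dR is mol/g
* diffusion coefficients: m^2/s; radii: nm
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, ParameterError

KB = 1.380649e-23  # Boltzmann constant, J/K
N_AVOGADRO = 6.02214076e23  # 1/mol

#: Detector geometry: eight angles at 8 degree increments, 30-86 degrees.
DEFAULT_ANGLES_DEG = np.arange(30.0, 87.0, 8.0)


@dataclass(frozen=True)
class ScatteringCalibration:
    """Optical and physical constants of a scattering experiment."""

    rr_std: float  # absolute Rayleigh ratio of the toluene standard, 1/cm
    conc_g_l: float  # solute concentration, g/l
    n0: float = 1.496  # refractive index of the goniometer bath (toluene)
    n: float = 1.332  # refractive index of the solvent (water)
    lambda0_nm: float = 632.8  # laser vacuum wavelength
    dndc_ml_g: float = 0.187  # refractive index increment
    eta_mpas: float = 0.891  # solvent dynamic viscosity, mPa s
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        for name in (
            "rr_std", "conc_g_l", "n0", "n", "lambda0_nm",
            "dndc_ml_g", "eta_mpas", "temperature_K",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"calibration field {name!r} must be positive")


@dataclass
class ScatteringFrame:
    """One time point of a multi-angle SLS/DLS acquisition."""

    t_s: float
    angles_deg: np.ndarray
    r_sol: np.ndarray
    r_solv: np.ndarray
    r_std: np.ndarray
    tau_s: np.ndarray | None = None  # DLS lag grid
    g1: np.ndarray | None = None  # (n_angles, n_lags) field correlation

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        for name in ("r_sol", "r_solv", "r_std"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ParameterError("angles must be strictly increasing")
        for name in ("r_sol", "r_solv", "r_std"):
            if getattr(self, name).shape != self.angles_deg.shape:
                raise ParameterError(f"{name} must match the angle grid")
        if self.tau_s is not None:
            self.tau_s = np.asarray(self.tau_s, dtype=float)
            self.g1 = np.asarray(self.g1, dtype=float)
            if np.any(np.diff(self.tau_s) <= 0):
                raise ParameterError("tau grid must be strictly increasing")
            if self.g1.shape != (self.angles_deg.size, self.tau_s.size):
                raise ParameterError("g1 must have shape (n_angles, n_lags)")
            if np.any(self.g1[:, 0] > 1.0 + 0.05):
                raise ParameterError("g1(tau->0) exceeds 1 beyond tolerance")


@dataclass
class LsFitResult:
    """Per-frame scattering evaluation result."""

    t_s: float = np.nan
    Mw_g_mol: float = np.nan
    Rg_nm: float = np.nan
    A2_ml_mol_g2: float | None = None
    D_per_angle_m2_s: np.ndarray | None = None
    Dz_m2_s: float = np.nan
    C_slope: float = np.nan
    k2: float = np.nan
    Rh_nm: float = np.nan
    rho: float = np.nan
    flags: list[str] = field(default_factory=list)


def momentum_transfer(theta_deg, n: float, lambda0_nm: float):
    """Scattering vector magnitude q = (4 pi n / lambda0) sin(theta/2), 1/nm."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg < 0) or np.any(theta_deg >= 180):
        raise ParameterError("theta must lie in [0, 180) degrees")
    return 4.0 * np.pi * n / lambda0_nm * np.sin(np.radians(theta_deg) / 2.0)


def excess_rayleigh(
    r_sol, r_solv, r_std, rr_std: float
) -> tuple[np.ndarray, np.ndarray]:
    """Excess Rayleigh ratio dR = RR_std * (r_sol - r_solv) / r_std per angle.

    Returns ``(dR, usable)`` where ``usable`` flags angles with dR > 0;
    angles where the solvent scatters more than the solution are excluded
    from downstream fits rather than failing the frame.
    """
    r_sol = np.asarray(r_sol, dtype=float)
    r_solv = np.asarray(r_solv, dtype=float)
    r_std = np.asarray(r_std, dtype=float)
    if np.any(r_std <= 0):
        raise ParameterError("standard intensities must be positive")
    d_r = rr_std * (r_sol - r_solv) / r_std
    return d_r, d_r > 0


def contrast_factor_from(n0: float, lambda0_nm: float, dndc_ml_g: float) -> float:
    """Optical contrast factor K = 4 pi^2 n0^2 (dn/dc)^2 / (N_A lambda^4).

    Computed in cm/g/mol units (lambda in cm, dn/dc in cm^3/g) so that
    ``K * c / dR`` with c in g/cm^3 and dR in 1/cm is mol/g, i.e. 1/Mw.
    """
    lam_cm = lambda0_nm * 1e-7
    return 4.0 * np.pi**2 * n0**2 * dndc_ml_g**2 / (N_AVOGADRO * lam_cm**4)


def contrast_factor(calib: ScatteringCalibration) -> float:
    """Contrast factor of a calibration record (see :func:`contrast_factor_from`)."""
    return contrast_factor_from(calib.n0, calib.lambda0_nm, calib.dndc_ml_g)


def _linear_lstsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line fit; returns (intercept, slope)."""
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def zimm_fit(
    q_nm: np.ndarray,
    d_r: np.ndarray,
    calib: ScatteringCalibration,
    conc_g_l=None,
) -> LsFitResult:
    """Zimm linearization: K c / dR = 1/Mw + Rg^2 q^2 / (3 Mw) + 2 A2 c.

    With a single concentration the ``2 A2 c`` term is dropped (flagged);
    with per-point concentrations supplied A2 is estimated as well.
    """
    q_nm = np.asarray(q_nm, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    keep = d_r > 0
    if keep.sum() < 3:
        raise FitError("need >= 3 usable angles for a Zimm fit")
    flags = [] if keep.all() else ["angles_dropped"]

    result = LsFitResult(flags=flags)
    if conc_g_l is None:
        c_gcm3 = calib.conc_g_l * 1e-3
        y = contrast_factor(calib) * c_gcm3 / d_r[keep]
        intercept, slope = _linear_lstsq(q_nm[keep] ** 2, y)
        result.A2_ml_mol_g2 = None
        result.flags.append("a2_dropped_single_concentration")
    else:
        conc = np.asarray(conc_g_l, dtype=float) * 1e-3  # g/cm^3
        y = contrast_factor(calib) * conc[keep] / d_r[keep]
        design = np.column_stack(
            [np.ones(keep.sum()), q_nm[keep] ** 2, 2.0 * conc[keep]]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope = float(coef[0]), float(coef[1])
        result.A2_ml_mol_g2 = float(coef[2])
    if intercept <= 0:
        raise FitError("non-positive Zimm intercept; cannot form Mw")
    result.Mw_g_mol = 1.0 / intercept
    rg2 = 3.0 * slope / intercept
    if rg2 < 0:
        result.Rg_nm = 0.0
        result.flags.append("negative_rg2")
    else:
        result.Rg_nm = float(np.sqrt(rg2))
    return result


def guinier_fit(
    q_nm: np.ndarray,
    d_r: np.ndarray,
    calib: ScatteringCalibration,
    max_q_rg: float | None = None,
) -> LsFitResult:
    """Guinier linearization: ln(K c / dR) = ln(1/Mw) - (Rg^2 / 3) q^2.

    ``max_q_rg`` enables an iterative fit-window trim: angles with
    q * Rg_fit above the limit are removed and the line is refitted, which
    keeps the linearization inside its regime of validity for large
    particles.  A warning is emitted when the final window still has
    q * Rg > 1.3 at the largest retained angle.
    """
    q_nm = np.asarray(q_nm, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    c_gcm3 = calib.conc_g_l * 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        kc_dr = contrast_factor(calib) * c_gcm3 / d_r
    keep = np.isfinite(kc_dr) & (kc_dr > 0)
    flags = [] if keep.all() else ["angles_dropped"]
    if keep.sum() < 3:
        raise FitError("fewer than 3 angles with positive K c / dR")

    # ln(Kc/dR) = ln(1/Mw) + (Rg^2/3) q^2: the inverse scattered intensity
    # RISES with q^2, so Rg^2 comes from a positive slope.
    q_fit, y_fit = q_nm[keep], np.log(kc_dr[keep])
    for _ in range(q_fit.size):
        intercept, slope = _linear_lstsq(q_fit**2, y_fit)
        rg = float(np.sqrt(3.0 * slope)) if slope > 0 else 0.0
        if max_q_rg is None:
            break
        inside = q_fit * rg <= max_q_rg
        if inside.all() or inside.sum() < 3:
            break
        q_fit, y_fit = q_fit[inside], y_fit[inside]
        flags = list(set(flags) | {"qrg_window_trimmed"})

    if slope <= 0:
        flags.append("negative_rg2")
    if q_fit[-1] * rg > 1.3:
        warnings.warn(
            "Guinier fit outside its validity window (q*Rg > 1.3 at the "
            "largest angle)", stacklevel=2,
        )
        flags.append("qrg_above_1.3")
    return LsFitResult(Mw_g_mol=float(np.exp(-intercept)), Rg_nm=rg, flags=flags)


def cumulant_fit(
    tau_s: np.ndarray,
    g1: np.ndarray,
    q_nm: float,
    min_g1_fraction: float = 0.1,
) -> tuple[float, float, float]:
    """Second-order cumulant fit ln g1 = A - q^2 D tau + q^4 k2 tau^2.

    The fit window is restricted to lags where ``g1`` stays above
    ``min_g1_fraction`` of its initial value (and above zero).  Returns
    ``(D_m2_s, k2, A)`` with D in m^2/s.
    """
    tau_s = np.asarray(tau_s, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    window = (g1 > 0) & (g1 > min_g1_fraction * g1[0])
    if window.sum() < 3:
        raise FitError("fewer than 3 usable lags in the cumulant window")
    x = tau_s[window]
    y = np.log(g1[window])
    design = np.column_stack([np.ones_like(x), x, x**2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, c1, c2 = (float(v) for v in coef)
    if c1 >= 0:
        raise FitError("correlation function does not decay")
    q_m = q_nm * 1e9  # 1/m
    d_coef = -c1 / q_m**2
    k2 = c2 / q_m**4
    return d_coef, k2, a0


def extrapolate_Dz(
    d_per_angle: np.ndarray,
    q_nm: np.ndarray,
    rg_nm: float | None = None,
) -> tuple[float, float, float | None, list[str]]:
    """Extrapolate apparent D to q^2 = 0: D = Dz (1 + q^2 Rg^2 C).

    The concentration term ``k_d c`` is intentionally not estimated.
    Returns ``(Dz, slope, C, flags)``; the slope is d D / d q^2 with q in
    1/nm.  With fewer than 3 valid angles the mean D is returned, flagged.
    """
    d_per_angle = np.asarray(d_per_angle, dtype=float)
    q_nm = np.asarray(q_nm, dtype=float)
    valid = np.isfinite(d_per_angle)
    if valid.sum() < 3:
        dz = float(np.nanmean(d_per_angle))
        return dz, 0.0, None, ["fallback_mean_D"]
    intercept, slope = _linear_lstsq(q_nm[valid] ** 2, d_per_angle[valid])
    c_coef = None
    if rg_nm is not None and rg_nm > 0 and intercept != 0:
        c_coef = slope / (intercept * rg_nm**2)
    return intercept, slope, c_coef, []


def stokes_einstein(dz_m2_s: float, calib: ScatteringCalibration) -> float:
    """Hydrodynamic radius Rh = kB T / (6 pi eta Dz), returned in nm."""
    if dz_m2_s <= 0:
        raise ParameterError("Dz must be positive")
    eta = calib.eta_mpas * 1e-3  # Pa s
    rh_m = KB * calib.temperature_K / (6.0 * np.pi * eta * dz_m2_s)
    return rh_m * 1e9


def diffusion_from_radius(rh_nm, calib: ScatteringCalibration):
    """Inverse of :func:`stokes_einstein`: D in m^2/s for a radius in nm."""
    eta = calib.eta_mpas * 1e-3
    return KB * calib.temperature_K / (6.0 * np.pi * eta * np.asarray(rh_nm) * 1e-9)


def rho_ratio(rg_nm: float, rh_nm: float) -> float:
    """Structure-sensitive ratio rho = Rg / Rh (0.775 for solid spheres)."""
    if rh_nm <= 0:
        raise ParameterError("Rh must be positive")
    return rg_nm / rh_nm


def analyze_frame(
    frame: ScatteringFrame,
    calib: ScatteringCalibration,
    max_q_rg: float = 1.3,
) -> LsFitResult:
    """Full single-frame chain: dR -> Guinier -> cumulants -> Dz -> Rh -> rho."""
    q_nm = momentum_transfer(frame.angles_deg, calib.n, calib.lambda0_nm)
    d_r, usable = excess_rayleigh(frame.r_sol, frame.r_solv, frame.r_std, calib.rr_std)
    d_r = np.where(usable, d_r, np.nan)
    sls = guinier_fit(q_nm, np.nan_to_num(d_r, nan=-1.0), calib, max_q_rg=max_q_rg)
    result = LsFitResult(
        t_s=frame.t_s, Mw_g_mol=sls.Mw_g_mol, Rg_nm=sls.Rg_nm, flags=list(sls.flags)
    )
    if frame.tau_s is None or frame.g1 is None:
        result.flags.append("no_dls_data")
        return result

    d_angles = np.full(q_nm.size, np.nan)
    k2s = np.full(q_nm.size, np.nan)
    for i in range(q_nm.size):
        try:
            d_angles[i], k2s[i], _ = cumulant_fit(frame.tau_s, frame.g1[i], q_nm[i])
        except FitError:
            result.flags.append(f"cumulant_failed_angle_{i}")
    result.D_per_angle_m2_s = d_angles
    result.k2 = float(np.nanmean(k2s)) if np.isfinite(k2s).any() else np.nan
    dz, slope, c_coef, dz_flags = extrapolate_Dz(d_angles, q_nm, result.Rg_nm)
    result.Dz_m2_s = dz
    result.C_slope = slope
    result.flags.extend(dz_flags)
    if np.isfinite(dz) and dz > 0:
        result.Rh_nm = stokes_einstein(dz, calib)
        result.rho = rho_ratio(result.Rg_nm, result.Rh_nm)
    else:
        result.flags.append("invalid_Dz")
    return result


def detect_induction_time(
    t_s: np.ndarray,
    mw: np.ndarray,
    baseline: np.ndarray,
    n_consecutive: int = 3,
    n_sigma: float = 3.0,
) -> float | None:
    """First time Mw exceeds baseline mean + n_sigma * SD for
    ``n_consecutive`` consecutive frames; None when never exceeded."""
    baseline = np.asarray(baseline, dtype=float)
    mw = np.asarray(mw, dtype=float)
    level = baseline.mean() + n_sigma * baseline.std(ddof=0)
    level += 1e-9 * abs(baseline.mean())  # guard for noiseless baselines
    above = mw > level
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= n_consecutive:
            return float(t_s[i - n_consecutive + 1])
    return None


def analyze_series(
    frames: Sequence[ScatteringFrame],
    calib: ScatteringCalibration,
    n_baseline: int | None = None,
    max_q_rg: float = 1.3,
) -> tuple[pd.DataFrame, float | None, list[str]]:
    """Evaluate a time series of frames and detect the induction time.

    Baseline frames are those with t < 0 (pre-addition) unless
    ``n_baseline`` explicitly marks the first frames as baseline.  Returns
    ``(results_table, induction_time_s, series_flags)``.
    """
    if len(frames) == 0:
        raise ParameterError("empty frame list")
    times = np.array([f.t_s for f in frames])
    if np.any(np.diff(times) <= 0):
        raise ParameterError("frames must be strictly time-ordered")

    rows = []
    for frame in frames:
        res = analyze_frame(frame, calib, max_q_rg=max_q_rg)
        rows.append(
            {
                "t_s": res.t_s,
                "Mw_g_mol": res.Mw_g_mol,
                "Rg_nm": res.Rg_nm,
                "Dz_m2_s": res.Dz_m2_s,
                "Rh_nm": res.Rh_nm,
                "rho": res.rho,
                "flags": ";".join(res.flags),
            }
        )
    table = pd.DataFrame(rows)

    series_flags: list[str] = []
    if n_baseline is not None:
        base = table["Mw_g_mol"].to_numpy()[:n_baseline]
    else:
        base = table.loc[table["t_s"] < 0, "Mw_g_mol"].to_numpy()
    if base.size == 0:
        series_flags.append("no_baseline_frames")
        return table, None, series_flags
    induction = detect_induction_time(
        table["t_s"].to_numpy(), table["Mw_g_mol"].to_numpy(), base
    )
    return table, induction, series_flags
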