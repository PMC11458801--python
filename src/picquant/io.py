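"""Readers/writers for the standard on-disk formats of the pipeline.

Images are multichannel TIFF with a YAML sidecar holding band metadata;
traces, spectra, scattering frames and results are plain CSV with fixed
column schemas.  All writers are deterministic (no timestamps) so that
rerunning a generation step yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import RoiSet, SpectralImage
from .errors import SchemaError
from .frap import FrapTrace
from .scattering import ScatteringCalibration, ScatteringFrame
from .uvvis import AbsorbanceRamp

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------- images

def write_spectral_image(path: Path, image: SpectralImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.channels)
    sidecar = {
        "bands_nm": [list(b) for b in image.bands_nm],
        "full_scale": int(image.full_scale),
        "pixel_size_um": image.pixel_size_um,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_spectral_image(path: Path) -> SpectralImage:
    path = Path(path)
    channels = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return SpectralImage(
        channels=channels,
        bands_nm=tuple(tuple(b) for b in meta["bands_nm"]),
        full_scale=meta["full_scale"],
        pixel_size_um=meta["pixel_size_um"],
    )


def write_roiset(path: Path, rois: RoiSet) -> None:
    """Masks as a stacked uint8 TIFF plus a YAML name index."""
    path = Path(path)
    names = sorted(rois.masks)
    stack = np.stack([rois.masks[n].astype(np.uint8) for n in names])
    tifffile.imwrite(path, stack)
    path.with_suffix(".yaml").write_text(yaml.safe_dump({"masks": names}))


def read_roiset(path: Path) -> RoiSet:
    path = Path(path)
    stack = tifffile.imread(path)
    names = yaml.safe_load(path.with_suffix(".yaml").read_text())["masks"]
    return RoiSet({n: stack[i].astype(bool) for i, n in enumerate(names)})


# ---------------------------------------------------------------- tables

def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def write_frap_trace(path: Path, trace: FrapTrace) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.t_s,
            "bleached": trace.bleached,
            "reference": trace.reference if trace.reference is not None else np.nan,
            "background": trace.background if trace.background is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_frap_trace(path: Path) -> FrapTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["t_s", "bleached", "reference", "background"], "FRAP trace")
    ref = df["reference"].to_numpy()
    bg = df["background"].to_numpy()
    return FrapTrace(
        t_s=df["t_s"].to_numpy(),
        bleached=df["bleached"].to_numpy(),
        reference=None if np.isnan(ref).all() else ref,
        background=None if np.isnan(bg).all() else bg,
    )


def write_scattering_frames(
    sls_path: Path, dls_path: Path, frames: list[ScatteringFrame]
) -> None:
    sls_rows, dls_rows = [], []
    for frame in frames:
        for j, angle in enumerate(frame.angles_deg):
            sls_rows.append(
                {
                    "t_s": frame.t_s,
                    "angle_deg": angle,
                    "r_sol": frame.r_sol[j],
                    "r_solv": frame.r_solv[j],
                    "r_std": frame.r_std[j],
                }
            )
            if frame.tau_s is not None:
                for tau, g1 in zip(frame.tau_s, frame.g1[j]):
                    dls_rows.append(
                        {"t_s": frame.t_s, "angle_deg": angle, "tau_s": tau, "g1": g1}
                    )
    pd.DataFrame(sls_rows).to_csv(sls_path, index=False, float_format=FLOAT_FMT)
    pd.DataFrame(dls_rows).to_csv(dls_path, index=False, float_format=FLOAT_FMT)


def read_scattering_frames(
    sls_path: Path, dls_path: Path | None = None
) -> list[ScatteringFrame]:
    sls = pd.read_csv(sls_path)
    _require_columns(sls, ["t_s", "angle_deg", "r_sol", "r_solv", "r_std"], "SLS table")
    dls = None
    if dls_path is not None and Path(dls_path).exists():
        dls = pd.read_csv(dls_path)
        _require_columns(dls, ["t_s", "angle_deg", "tau_s", "g1"], "DLS table")
    frames = []
    for t, group in sls.groupby("t_s", sort=True):
        group = group.sort_values("angle_deg")
        tau = g1 = None
        if dls is not None:
            sub = dls[dls["t_s"] == t]
            if len(sub):
                tau = np.sort(sub["tau_s"].unique())
                g1 = np.stack(
                    [
                        sub[sub["angle_deg"] == a].sort_values("tau_s")["g1"].to_numpy()
                        for a in group["angle_deg"]
                    ]
                )
        frames.append(
            ScatteringFrame(
                t_s=float(t),
                angles_deg=group["angle_deg"].to_numpy(),
                r_sol=group["r_sol"].to_numpy(),
                r_solv=group["r_solv"].to_numpy(),
                r_std=group["r_std"].to_numpy(),
                tau_s=tau,
                g1=g1,
            )
        )
    return frames


def write_calibration(path: Path, calib: ScatteringCalibration) -> None:
    Path(path).write_text(yaml.safe_dump(calib.__dict__, sort_keys=True))


def read_calibration(path: Path) -> ScatteringCalibration:
    return ScatteringCalibration(**yaml.safe_load(Path(path).read_text()))


def write_ramp(path: Path, ramp: AbsorbanceRamp) -> None:
    n_wl = ramp.wavelength_nm.size
    df = pd.DataFrame(
        {
            "temperature_C": np.repeat(ramp.temperatures_C, n_wl),
            "wavelength_nm": np.tile(ramp.wavelength_nm, ramp.temperatures_C.size),
            "absorbance": ramp.absorbance.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_ramp(path: Path) -> AbsorbanceRamp:
    df = pd.read_csv(path)
    _require_columns(df, ["temperature_C", "wavelength_nm", "absorbance"], "ramp table")
    temps = df["temperature_C"].unique()  # file order: descending
    wl = np.sort(df["wavelength_nm"].unique())
    spectra = np.stack(
        [
            df[df["temperature_C"] == t].sort_values("wavelength_nm")["absorbance"].to_numpy()
            for t in temps
        ]
    )
    return AbsorbanceRamp(temperatures_C=temps, wavelength_nm=wl, absorbance=spectra)


# ------------------------------------------------------------- manifests

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path: Path, config: dict) -> None:
    payload = {"config": config, "config_sha256": config_hash(config)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
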