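import numpy as np
import pytest

from picquant.scattering import DEFAULT_ANGLES_DEG, ScatteringCalibration, momentum_transfer
from picquant.synth import CellScene, DropletGrowthModel, generate_cell_image


@pytest.fixture(scope="session")
def calib() -> ScatteringCalibration:
    return ScatteringCalibration(rr_std=1.35e-5, conc_g_l=0.008)


@pytest.fixture(scope="session")
def q_grid(calib) -> np.ndarray:
    return momentum_transfer(DEFAULT_ANGLES_DEG, calib.n, calib.lambda0_nm)


@pytest.fixture(scope="session")
def growth_model() -> DropletGrowthModel:
    return DropletGrowthModel(
        nucleation_time_s=100.0,
        final_radius_nm=50.0,
        growth_tau_s=80.0,
        baseline_Mw_g_mol=1.0e5,
        baseline_Rh_nm=3.0,
    )


@pytest.fixture(scope="session")
def clean_scene_10pct():
    """Noiseless 10%-aggregate scene, generated once per session."""
    return generate_cell_image(CellScene(planted_aggregate_fraction=0.10, seed=7))


@pytest.fixture(scope="session")
def clean_scene_empty():
    return generate_cell_image(CellScene(planted_aggregate_fraction=0.0, seed=11))
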