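import numpy as np
import pytest

import lakechl.synthetic_data as synth
from lakechl.geometry import build_valid_water_mask


@pytest.fixture(scope="session")
def circle_geometry():
    """50x50 grid, 60 m cells, circular lake of radius 900 m."""
    return synth.generate_lake_geometry(
        50, 50, 60.0, {"radius_m": 900.0, "max_depth_m": 30.0}, seed=0
    )


@pytest.fixture(scope="session")
def small_world():
    """Small lake + truth + noiseless scene series + valid-water mask."""
    geo = synth.generate_lake_geometry(
        30, 30, 60.0, {"radius_m": 700.0, "max_depth_m": 25.0}, seed=1
    )
    geo.buffer_distance = 120.0
    secchi = synth.generate_secchi_samples(100, median=3.0, sigma=0.3, seed=2)
    vwm = build_valid_water_mask(geo, secchi)
    truth = synth.make_lake_truth(
        geo, base_chl=8.0, n_scenes=5, temporal_cv=0.0, noise_cv=0.0, seed=3
    )
    scenes = synth.generate_scene_series(
        truth, cloud_fraction=0.0, valid_water_mask=vwm, seed=4
    )
    return geo, truth, scenes, vwm


def diagonal_pattern(mask: np.ndarray, amplitude: float) -> np.ndarray:
    """Steep diagonal multiplicative ramp, mean 1 over the mask."""
    rows, cols = mask.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    t = cc + 0.37 * rr
    t = (t - t.min()) / (t.max() - t.min())
    pat = 1.0 - amplitude + 2.0 * amplitude * t
    return pat / pat[mask].mean()
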