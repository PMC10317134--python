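"""Shared fixtures: a proportionally scaled detector geometry and small scan
scenes keep the suite fast while preserving every d-spacing ↔ radius
relationship of the full-size instrument."""

import numpy as np
import pytest

import diffscan as dsn

# 128-pixel detector at 22.5 cm: every diffraction radius is exactly 1/4 of
# its value on the 512-pixel detector at 90 cm, so rings stay in proportion.
SCALE = 0.25


@pytest.fixture(scope="session")
def small_geom() -> dsn.DetectorGeometry:
    return dsn.DetectorGeometry(n_pixels=128, camera_length_m=0.225)


@pytest.fixture(scope="session")
def small_models(small_geom):
    return dsn.default_frame_models(scale=SCALE)


@pytest.fixture(scope="session")
def full_geom() -> dsn.DetectorGeometry:
    return dsn.DetectorGeometry()


@pytest.fixture(scope="session")
def two_region_scene():
    """16×16 scene: an amorphous-ice hole and a crystalline patch in carbon."""
    return dsn.SceneSpec(
        grid_shape=(16, 16),
        regions=[
            (dsn.ClassLabel.amorphous_ice, [(1.6, 1.6), (8.2, 0.8), (9.8, 8.2), (2.4, 9.8)]),
            (dsn.ClassLabel.crystalline_ice, [(10.2, 10.2), (15.4, 10.6), (15.4, 15.4), (10.6, 15.4)]),
        ],
        mixed_band=1,
    )


@pytest.fixture(scope="session")
def small_scan(two_region_scene, small_models, small_geom):
    """One simulated 16×16 scan of 128-pixel frames, reused across tests."""
    scan_geom = dsn.ScanGeometry(grid_shape=(16, 16))
    return dsn.simulate_scan(
        two_region_scene, small_models, small_geom, scan_geom, seed=42,
        drift_px=(1.5, -1.0),
    )


@pytest.fixture(scope="session")
def small_features(small_scan):
    from diffscan.pipeline import extract_features

    return extract_features(small_scan, crop_radius=37, downsample=3)


def make_centered(pixels: np.ndarray, center=None, invalid=None) -> "dsn.CenteredFrame":
    """Helper: centre a square frame at its geometric middle (or ``center``)."""
    n = pixels.shape[0]
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    return dsn.center_frame(pixels, center, invalid_mask=invalid)
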