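"""Shared fixtures: phantoms and small, fast render configurations.

Unit tests use a short root and a truncated recording so each render takes
well under a second; the acceptance suite uses the full study-condition
defaults (568 frames / 180 s on a 3 mm root).
"""

import numpy as np
import pytest

from rootwave.rootsim import (
    Camera,
    DEFAULT_GEOMETRY,
    RootGeometry,
    build_phantom,
)


@pytest.fixture(scope="session")
def phantom():
    """Full study-condition phantom (3 mm root at 2 µm/px)."""
    return build_phantom(DEFAULT_GEOMETRY, Camera().pixel_size_um)


@pytest.fixture(scope="session")
def small_geometry():
    """Short root for fast unit-level renders."""
    return RootGeometry(length_um=800.0, radius_um=60.0)


@pytest.fixture(scope="session")
def small_phantom(small_geometry):
    return build_phantom(small_geometry, 2.0)


@pytest.fixture()
def small_camera():
    """80-frame quick-look camera: same optics/noise, truncated recording."""
    return Camera(n_frames=80, seed=0)


def arclength_of_positions(phantom, positions_um):
    """Map longitudinal kymograph positions (frame x, µm) to arclength s."""
    apex_x_local = phantom.geometry.centerline[0, 0] - phantom.origin_um[0]
    return np.asarray(positions_um) - apex_x_local
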