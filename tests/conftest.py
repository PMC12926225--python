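import numpy as np
import pytest

from eitgraph import (
    build_current_patterns,
    build_head_geometry,
    build_mesh,
    uniform_electrodes,
)


@pytest.fixture(scope="session")
def geom2d():
    return build_head_geometry(2)


@pytest.fixture(scope="session")
def disc_mesh(geom2d):
    """~200-node 2D head mesh with 16 electrodes."""
    return build_mesh(geom2d, 8)


@pytest.fixture(scope="session")
def disc_mesh_fine(geom2d):
    return build_mesh(geom2d, 12)


@pytest.fixture(scope="session")
def setup2d(geom2d):
    return (
        uniform_electrodes(geom2d.n_electrodes),
        build_current_patterns(geom2d.n_electrodes, "adjacent", 1.0),
    )


@pytest.fixture(scope="session")
def geom3d():
    return build_head_geometry(3)


@pytest.fixture(scope="session")
def ball_mesh(geom3d):
    """Small 3D layered-ball mesh with 32 electrodes."""
    return build_mesh(geom3d, 5)


@pytest.fixture(scope="session")
def setup3d(geom3d):
    return (
        uniform_electrodes(geom3d.n_electrodes),
        build_current_patterns(geom3d.n_electrodes, "pairwise", 1.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
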