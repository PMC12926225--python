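"""Deterministic small fixtures for tests and demos.

Every fixture is generated procedurally from a fixed specification, so
tests and demos never depend on shipped data files.  ``make_fixture``
materializes a fixture to disk (HDF5 + VTK); the ``*_mesh``/``*_dataset``
helpers return the in-memory objects and are what the test-suite uses.
"""

from __future__ import annotations

import os

import numpy as np

from .mesh import FEMesh
from .phantoms import build_head_geometry, build_mesh
from .train import make_context, make_training_set


def single_triangle() -> FEMesh:
    return FEMesh(
        nodes=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        simplices=np.array([[0, 1, 2]]),
    )


def single_tet() -> FEMesh:
    return FEMesh(
        nodes=np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
        ),
        simplices=np.array([[0, 1, 2, 3]]),
    )


def disc_meshes(resolutions=(8, 12, 18)) -> list:
    """Homogeneous-disc head meshes at increasing refinement."""
    geom = build_head_geometry(2, ellipse_ratio=1.0)
    return [build_mesh(geom, r) for r in resolutions]


def disc_coarse():
    """2D head mesh with 16 electrodes, suitable for inverse problems."""
    geom = build_head_geometry(2)
    return geom, build_mesh(geom, 16)


def ball3d_coarse():
    """Coarse 3D layered ball phantom mesh with 32 electrodes."""
    geom = build_head_geometry(3)
    return geom, build_mesh(geom, 7)


def demo2d_dataset(seed: int = 7, n_pairs: int = 24):
    """24 LD/truth pairs (20 train / 4 validation) on coarse 2D meshes."""
    ctx = make_context(2, sim_resolution=20, inv_resolution=12)
    rng = np.random.default_rng(seed)
    samples = make_training_set(n_pairs, ctx, rng)
    return ctx, samples


FIXTURES = {
    "disc-coarse": "2D head mesh, 16 electrodes",
    "ball3d-coarse": "3D layered ball phantom mesh, 32 electrodes",
    "demo2d": "24 simulated LD/truth pairs (20 train / 4 validation)",
}


def make_fixture(name: str, out_dir: str = "fixtures"):
    """Materialize a named fixture under ``out_dir``; idempotent."""
    from . import io as eio

    if name not in FIXTURES:
        raise ValueError(
            "unknown fixture %r; available: %s" % (name, sorted(FIXTURES))
        )
    os.makedirs(out_dir, exist_ok=True)
    if name == "disc-coarse":
        _, mesh = disc_coarse()
        eio.write_vtk(os.path.join(out_dir, "disc-coarse.vtk"), mesh)
    elif name == "ball3d-coarse":
        _, mesh = ball3d_coarse()
        eio.write_vtk(os.path.join(out_dir, "ball3d-coarse.vtk"), mesh)
    elif name == "demo2d":
        ctx, samples = demo2d_dataset()
        eio.save_samples(os.path.join(out_dir, "demo2d.h5"), samples)
        eio.write_vtk(
            os.path.join(out_dir, "demo2d-mesh.vtk"),
            ctx.inv_mesh,
            point_data={"ld_sample0": samples[0].ld,
                        "truth_sample0": samples[0].truth},
        )
    return out_dir
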