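"""Image-quality metrics for difference reconstructions.

All nodal integrals use lumped nodal measures (each simplex spreads its
area/volume evenly over its vertices), so MSE is a volume-weighted mean
and region measures approximate true areas/volumes.  Detected regions are
defined by thresholding each image separately at half its (positive)
maximum; localization and volume errors compare half-max regions of the
reconstruction and the truth.  PSNR uses the truth's maximum magnitude as
the peak and is undefined for an identically zero truth (reported as NaN,
with +inf for an exact zero-error match).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import FEMesh


@dataclass
class MetricRecord:
    mse: float
    psnr: float          # dB; NaN when undefined, +inf for exact match
    cm_error: float      # cm; NaN when a half-max region is empty
    volume_error: float  # cm^3 (cm^2 in 2D); empty regions count as 0


def _check_shared_mesh(a, b, mesh):
    if len(a) != mesh.n_nodes or len(b) != mesh.n_nodes:
        raise ValueError("images do not live on the given mesh")


def image_mse_psnr(recon, truth, mesh: FEMesh):
    """Volume-weighted MSE and PSNR = 10 log10(peak^2 / MSE)."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    _check_shared_mesh(recon, truth, mesh)
    w = mesh.nodal_volumes()
    mse = float(np.sum(w * (recon - truth) ** 2) / np.sum(w))
    peak = float(np.max(np.abs(truth)))
    if peak == 0.0:
        psnr = np.nan
    elif mse == 0.0:
        psnr = np.inf
    else:
        psnr = float(10.0 * np.log10(peak**2 / mse))
    return mse, psnr


def half_max_region(image, mesh: FEMesh):
    """Indicator of nodes >= half the positive maximum, and its measure."""
    image = np.asarray(image, dtype=float)
    peak = image.max() if image.size else 0.0
    if peak <= 0.0:
        ind = np.zeros(len(image), dtype=bool)
        return ind, 0.0
    ind = image >= 0.5 * peak
    measure = float(mesh.nodal_volumes()[ind].sum())
    return ind, measure


def _region_centroid(ind, mesh):
    w = mesh.nodal_volumes()[ind]
    return (w[:, None] * mesh.nodes[ind]).sum(axis=0) / w.sum()


def cm_error(recon, truth, mesh: FEMesh) -> float:
    """Distance between half-max-region centroids (cm); NaN if either
    region is empty (mirrors undefined cases for zero expansions)."""
    ri, _ = half_max_region(recon, mesh)
    ti, _ = half_max_region(truth, mesh)
    if not ri.any() or not ti.any():
        return np.nan
    return float(
        np.linalg.norm(_region_centroid(ri, mesh) - _region_centroid(ti, mesh))
    )


def volume_error(recon, truth, mesh: FEMesh) -> float:
    """Signed half-max measure difference: recon - truth (cm^3 / cm^2).

    A truth with no positive part has zero detected volume, so the error
    for a zero-change frame is simply the reconstruction's spurious
    half-max measure (artifact volume).
    """
    _, rv = half_max_region(recon, mesh)
    _, tv = half_max_region(truth, mesh)
    return float(rv - tv)


def evaluate_image(recon, truth, mesh: FEMesh) -> MetricRecord:
    mse, psnr = image_mse_psnr(recon, truth, mesh)
    return MetricRecord(
        mse=mse,
        psnr=psnr,
        cm_error=cm_error(recon, truth, mesh),
        volume_error=volume_error(recon, truth, mesh),
    )


# ---------------------------------------------------------------------------
# analytic bookkeeping for test-case hemorrhage volumes
# ---------------------------------------------------------------------------

def sphere_volume(diameter_mm: float) -> float:
    """Sphere volume in ml (= cm^3) from its diameter in mm."""
    if diameter_mm < 0:
        raise ValueError("diameter must be nonnegative")
    d_cm = diameter_mm / 10.0
    return np.pi / 6.0 * d_cm**3


def cylinder_volume(diameter_mm: float, height_mm: float) -> float:
    """Cylinder volume in ml from diameter and height in mm."""
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("cylinder dimensions must be positive")
    return np.pi / 4.0 * (diameter_mm / 10.0) ** 2 * (height_mm / 10.0)


def analytic_shape_volume(shape: str, *dims_mm) -> float:
    """Closed-form volume (ml) of a test shape or a growth step.

    ``("sphere", d)``, ``("cylinder", d, h)``, or
    ``("sphere_pair", d1, d2)`` for the volume change d1 -> d2.
    """
    if shape == "sphere":
        return sphere_volume(*dims_mm)
    if shape == "cylinder":
        return cylinder_volume(*dims_mm)
    if shape == "sphere_pair":
        d1, d2 = dims_mm
        return sphere_volume(d2) - sphere_volume(d1)
    raise ValueError("unknown shape: %r" % shape)
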