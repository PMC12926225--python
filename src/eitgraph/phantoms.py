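"""Randomized head phantoms with growing hemorrhages.

A phantom is a layered head domain (skin / skull / brain) with an
intracerebral hemorrhage simulated in two frames: an *initial* bleed (a
disc in 2D, a ball in 3D) and an *expanded* bleed (the initial shape plus
an attached half-ellipse / half-ellipsoid with a random direction).  Blood
is far more conductive than brain tissue, so the expansion appears as a
localized positive conductivity change between the frames.

Default tissue conductivities (S/m, ~1 kHz): skin and brain 0.06948,
skull 0.009, hemorrhage 0.312.  Per-phantom variability multiplies each
tissue value by a factor drawn uniformly from [0.75, 1.25]; the factors
are shared by both frames of a pair so the only change between frames is
the bleed expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    FEMesh,
    MeshError,
    assign_electrodes_2d,
    assign_electrodes_3d,
    ball_mesh_3d,
    disc_mesh_2d,
)

TISSUE_CONDUCTIVITY = {
    "skin": 0.06948,
    "skull": 0.009,
    "brain": 0.06948,
    "blood": 0.312,
}

DEFAULT_RADIUS_RANGE_CM = (1.5, 7.47)
PERTURBATION_RANGE = (0.75, 1.25)


class GeometryError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class HeadGeometry:
    """Fixed layered head geometry with boundary electrodes.

    2D: a slightly elliptical head outline (width = major extent) with 16
    equispaced boundary electrodes.  3D: a layered ball with 32 electrodes
    on four rings.  The skin and skull layer thicknesses are measured
    radially inward from the outer boundary.
    """

    dimension: int
    width: float = 18.0            # maximal extent, cm
    ellipse_ratio: float = 1.0     # 2D minor/major axis ratio
    skin_thickness: float = 0.7    # cm
    skull_thickness: float = 0.7   # cm
    n_electrodes: int = 16
    electrode_width: float = 2.0   # 2D arc length / 3D patch diameter, cm

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise GeometryError("dimension must be 2 or 3")
        if self.skin_thickness + self.skull_thickness >= self.width / 2:
            raise GeometryError("skull band exceeds head radius")
        if self.dimension == 2:
            # feasibility of non-overlapping equispaced electrodes
            perimeter = np.pi * self.width / 2 * (1 + self.ellipse_ratio)
            if self.n_electrodes * self.electrode_width >= perimeter:
                raise GeometryError(
                    "electrodes of width %.3g cm x %d cannot fit a %.3g cm "
                    "perimeter without overlap"
                    % (self.electrode_width, self.n_electrodes, perimeter)
                )

    # --- radial description -------------------------------------------------
    def outer_radius(self, theta):
        """Boundary radius at angle(s) theta (2D) or uniformly (3D)."""
        a = self.width / 2
        if self.dimension == 3:
            return np.full_like(np.asarray(theta, dtype=float), a)
        b = a * self.ellipse_ratio
        th = np.asarray(theta, dtype=float)
        return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

    @property
    def brain_radius_min(self) -> float:
        """Largest r such that the ball/disc of that radius about the origin
        lies entirely in the brain region."""
        rmin = self.width / 2 * (self.ellipse_ratio if self.dimension == 2 else 1.0)
        return rmin - self.skin_thickness - self.skull_thickness

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Tissue label per point: 0 skin, 1 skull, 2 brain."""
        pts = np.atleast_2d(points)
        r = np.linalg.norm(pts, axis=1)
        if self.dimension == 2:
            th = np.arctan2(pts[:, 1], pts[:, 0])
            rb = self.outer_radius(th)
        else:
            rb = np.full(len(pts), self.width / 2)
        lab = np.full(len(pts), 2, dtype=np.int64)
        lab[r > rb - self.skin_thickness - self.skull_thickness] = 1
        lab[r > rb - self.skin_thickness] = 0
        return lab

    def electrode_centers(self):
        if self.dimension == 2:
            return 2 * np.pi * np.arange(self.n_electrodes) / self.n_electrodes
        # four rings of n/4 electrodes at polar angles 50..120 deg
        per_ring = self.n_electrodes // 4
        dirs = []
        for i, pol in enumerate(np.deg2rad([50, 73, 96, 119])):
            for j in range(per_ring):
                az = 2 * np.pi * (j + 0.5 * (i % 2)) / per_ring
                dirs.append(
                    [
                        np.sin(pol) * np.cos(az),
                        np.sin(pol) * np.sin(az),
                        np.cos(pol),
                    ]
                )
        return np.asarray(dirs)


def build_head_geometry(dimension: int, **config) -> HeadGeometry:
    """Fixed (non-random) head geometry; see :class:`HeadGeometry`."""
    defaults = dict(n_electrodes=16 if dimension == 2 else 32)
    if dimension == 3:
        defaults["electrode_width"] = 3.0
    defaults.update(config)
    return HeadGeometry(dimension=dimension, **defaults)


def build_mesh(geometry: HeadGeometry, resolution: int) -> FEMesh:
    """Mesh the head geometry.

    2D: ``resolution`` = number of concentric rings (N = 1+3n(n+1)).
    3D: ``resolution`` = approximate shells count; shell spacing is
    radius/resolution.
    """
    if geometry.dimension == 2:
        nodes, simplices = disc_mesh_2d(geometry.outer_radius, resolution)
        patches = assign_electrodes_2d(
            nodes,
            simplices,
            geometry.electrode_centers(),
            [geometry.electrode_width] * geometry.n_electrodes,
        )
    else:
        R = geometry.width / 2
        nodes, simplices = ball_mesh_3d(R, R / resolution)
        patches = assign_electrodes_3d(
            nodes, simplices, geometry.electrode_centers(),
            geometry.electrode_width,
        )
    return FEMesh(nodes=nodes, simplices=simplices, electrode_patches=patches)


# ---------------------------------------------------------------------------
# Hemorrhage pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemorrhagePair:
    """Initial + expanded bleed with shared tissue perturbations.

    The initial bleed is a disc/ball (center, radius).  The expansion is a
    half-ellipse / half-ellipsoid centred at the same point: the full
    ellipsoid has the sampled main-axis length along ``direction`` and
    secondary semi-axes equal to the initial radius, restricted to the
    half-space ``(x - center) . direction >= 0``.  Their union is therefore
    connected by construction.
    """

    center: tuple
    radius: float
    direction: tuple
    axis_length: float
    perturbation: dict = field(default_factory=dict)
    tissue_values: dict = field(default_factory=lambda: dict(TISSUE_CONDUCTIVITY))

    def conductivity(self, tissue: str) -> float:
        return self.tissue_values[tissue] * self.perturbation.get(tissue, 1.0)

    @property
    def secondary_axis(self) -> float:
        return self.radius if self.radius > 0 else self.axis_length / 2

    def in_initial(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if self.radius <= 0:
            return np.zeros(len(pts), dtype=bool)
        return np.linalg.norm(pts - np.asarray(self.center), axis=1) <= self.radius

    def in_expansion(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        c = np.asarray(self.center)
        d = np.asarray(self.direction)
        rel = pts - c
        t = rel @ d
        perp = rel - np.outer(t, d)
        q = (t / self.axis_length) ** 2 + (
            np.linalg.norm(perp, axis=1) / self.secondary_axis
        ) ** 2
        return (q <= 1.0) & (t >= 0.0)

    def in_hemorrhage(self, points: np.ndarray, frame: str) -> np.ndarray:
        inside = self.in_initial(points)
        if frame == "expanded":
            inside = inside | self.in_expansion(points)
        elif frame != "initial":
            raise ValueError("frame must be 'initial' or 'expanded'")
        return inside

    def surface_samples(self, frame: str, n: int = 128) -> np.ndarray:
        """Points on the bleed's outer surface, for containment checks."""
        c = np.asarray(self.center)
        dim = len(c)
        if dim == 2:
            th = 2 * np.pi * np.arange(n) / n
            sph = np.column_stack([np.cos(th), np.sin(th)])
        else:
            from .mesh import _fibonacci_sphere

            sph = _fibonacci_sphere(n)
        out = []
        if self.radius > 0:
            out.append(c + self.radius * sph)
        if frame == "expanded":
            d = np.asarray(self.direction)
            t = sph @ d
            keep = sph[t >= 0]
            perp = keep - np.outer(keep @ d, d)
            pts = c + np.outer(keep @ d, d) * self.axis_length + perp * self.secondary_axis
            out.append(pts)
        return np.concatenate(out, axis=0) if out else np.zeros((0, dim))


def _unit_direction(rng, dim):
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def sample_hemorrhage_pair(
    geometry: HeadGeometry,
    rng: np.random.Generator,
    radius_range=DEFAULT_RADIUS_RANGE_CM,
    perturbation_range=PERTURBATION_RANGE,
    max_draws: int = 10_000,
) -> HemorrhagePair:
    """Draw a random hemorrhage pair inside the brain region.

    The initial radius and expansion main-axis length are uniform on
    ``radius_range``; the expansion direction is uniform on the circle /
    sphere.  A draw whose bleed would touch the skull is rejected and the
    *placement* (center, direction) redrawn, keeping the sampled sizes, so
    the accepted radius distribution stays uniform.
    """
    dim = geometry.dimension
    lo, hi = radius_range
    radius = float(rng.uniform(lo, hi))
    axis_length = float(rng.uniform(lo, hi))
    pert = {
        t: float(rng.uniform(*perturbation_range))
        for t in ("skin", "skull", "brain")
    }
    pert["blood"] = 1.0

    rb = geometry.brain_radius_min
    if radius >= rb or axis_length >= rb:
        raise SamplingError(
            "bleed of size %.2f/%.2f cm cannot fit the %.2f cm brain region"
            % (radius, axis_length, rb)
        )
    # centers with the initial ball guaranteed inside the brain
    c_max = rb - radius
    for _ in range(max_draws):
        if dim == 2:
            u = rng.random()
            r_c = c_max * np.sqrt(u)
        else:
            r_c = c_max * rng.random() ** (1 / 3)
        center = tuple(r_c * _unit_direction(rng, dim))
        direction = tuple(_unit_direction(rng, dim))
        pair = HemorrhagePair(
            center=center,
            radius=radius,
            direction=direction,
            axis_length=axis_length,
            perturbation=pert,
        )
        surf = pair.surface_samples("expanded", n=128 if dim == 2 else 256)
        if np.all(geometry.classify(surf) == 2):
            return pair
    raise SamplingError(
        "no admissible placement in %d draws for radius %.2f cm, axis %.2f cm"
        % (max_draws, radius, axis_length)
    )


def render_conductivity(
    geometry: HeadGeometry,
    pair: HemorrhagePair,
    frame: str,
    mesh: FEMesh,
) -> np.ndarray:
    """Nodal conductivity field (S/m) of the phantom in the given frame."""
    if mesh.dim != geometry.dimension:
        raise MeshError("mesh dimension does not match geometry")
    labels = geometry.classify(mesh.nodes)
    names = np.array(["skin", "skull", "brain"])
    sigma = np.array([pair.conductivity(t) for t in names])[labels]
    inside = pair.in_hemorrhage(mesh.nodes, frame)
    sigma[inside & (labels == 2)] = pair.conductivity("blood")
    return sigma


def true_difference(pair: HemorrhagePair, geometry: HeadGeometry, mesh: FEMesh):
    """Ground-truth conductivity change (expanded - initial) on mesh nodes."""
    s1 = render_conductivity(geometry, pair, "initial", mesh)
    s2 = render_conductivity(geometry, pair, "expanded", mesh)
    return s2 - s1
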