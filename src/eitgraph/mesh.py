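"""Finite-element meshes for head-shaped EIT domains.

Meshes are simplicial (triangles in 2D, tetrahedra in 3D) with node
coordinates in centimetres.  Electrodes are carried as lists of boundary
facets (edges / surface triangles) so the complete electrode model can
integrate over them.  Generation is fully procedural: structured point
layouts (concentric rings in 2D, Fibonacci-sphere shells in 3D) are
triangulated with Delaunay, which gives well-shaped simplices for the
convex, head-like domains used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree


class MeshError(ValueError):
    """Raised for inconsistent mesh / electrode configurations."""


@dataclass
class FEMesh:
    """Simplicial FE mesh with electrode boundary patches.

    Attributes
    ----------
    nodes : (N, d) float array, coordinates in cm.
    simplices : (E, d+1) int array, positively oriented.
    electrode_patches : list of (F_l, d) int arrays; each row is one
        boundary facet (edge in 2D, triangle in 3D) of electrode l.
    """

    nodes: np.ndarray
    simplices: np.ndarray
    electrode_patches: list = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.simplices = np.asarray(self.simplices, dtype=np.int64)
        self.simplices = _orient_positively(self.nodes, self.simplices)
        self._cache = {}

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_patches)

    def element_measures(self) -> np.ndarray:
        """Signed simplex measures (cm^d); positive after orientation."""
        if "meas" not in self._cache:
            self._cache["meas"] = _simplex_measures(self.nodes, self.simplices)
        return self._cache["meas"]

    def nodal_volumes(self) -> np.ndarray:
        """Lumped nodal measures: each simplex spreads its measure evenly
        over its d+1 vertices.  Sums to the total mesh measure."""
        if "nodal_vol" not in self._cache:
            meas = self.element_measures()
            vol = np.zeros(self.n_nodes)
            share = meas / (self.dim + 1)
            for k in range(self.dim + 1):
                np.add.at(vol, self.simplices[:, k], share)
            self._cache["nodal_vol"] = vol
        return self._cache["nodal_vol"]

    def total_measure(self) -> float:
        return float(self.element_measures().sum())

    def boundary_facets(self) -> np.ndarray:
        """Facets that belong to exactly one simplex, as sorted node tuples."""
        if "bfacets" not in self._cache:
            self._cache["bfacets"] = _boundary_facets(self.simplices, self.dim)
        return self._cache["bfacets"]

    def permuted(self, perm: np.ndarray) -> "FEMesh":
        """Mesh with nodes reordered: new index of old node i is perm[i]."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return FEMesh(
            nodes=self.nodes[inv],
            simplices=perm[self.simplices],
            electrode_patches=[perm[p] for p in self.electrode_patches],
        )


def _orient_positively(nodes, simplices):
    meas = _signed_measures(nodes, simplices)
    if np.any(np.abs(meas) < 1e-14):
        raise MeshError("degenerate (zero-measure) simplex in mesh")
    flip = meas < 0
    simplices = simplices.copy()
    simplices[flip, -2], simplices[flip, -1] = (
        simplices[flip, -1].copy(),
        simplices[flip, -2].copy(),
    )
    return simplices


def _signed_measures(nodes, simplices):
    d = nodes.shape[1]
    v = nodes[simplices[:, 1:]] - nodes[simplices[:, :1]]
    if d == 2:
        det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] * v[:, 1, 0]
        return det / 2.0
    det = np.linalg.det(v)
    return det / 6.0


def _simplex_measures(nodes, simplices):
    return np.abs(_signed_measures(nodes, simplices))


def _boundary_facets(simplices, dim):
    E = simplices.shape[0]
    faces = []
    nv = dim + 1
    for k in range(nv):
        idx = [j for j in range(nv) if j != k]
        faces.append(simplices[:, idx])
    faces = np.concatenate(faces, axis=0)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    return key[first[counts == 1]]


# ---------------------------------------------------------------------------
# 2D head-slice meshes
# ---------------------------------------------------------------------------

def disc_mesh_2d(radial_fn, n_rings: int) -> tuple[np.ndarray, np.ndarray]:
    """Structured triangulation of a star-shaped 2D domain.

    ``radial_fn(theta)`` gives the boundary radius.  Points are laid on
    ``n_rings`` concentric scaled copies of the boundary curve (ring k
    carries 6k points), then Delaunay-triangulated.
    """
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        m = 6 * k
        th = 2 * np.pi * (np.arange(m) + 0.5 * (k % 2)) / m
        r = radial_fn(th) * k / n_rings
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    pts = np.concatenate(pts, axis=0)
    tri = Delaunay(pts)
    return pts, tri.simplices


def assign_electrodes_2d(nodes, simplices, centers_theta, widths_cm) -> list:
    """Pick boundary edges within each electrode's arc.

    Electrode l is the arc of half-width ``widths_cm[l]/2`` (arc length)
    centred at boundary angle ``centers_theta[l]``.  An edge belongs to the
    electrode whose arc contains its midpoint angle.
    """
    bedges = _boundary_facets(simplices, 2)
    mids = nodes[bedges].mean(axis=1)
    ang = np.arctan2(mids[:, 1], mids[:, 0])
    rad = np.hypot(mids[:, 0], mids[:, 1])

    patches = []
    halfang = []
    for c, w in zip(centers_theta, widths_cm):
        # local boundary radius ~ radius of nearest edge midpoints
        d = np.abs(np.angle(np.exp(1j * (ang - c))))
        rloc = rad[np.argmin(d)]
        halfang.append(w / (2.0 * rloc))
    halfang = np.asarray(halfang)
    order = np.argsort(np.asarray(centers_theta))
    cs = np.asarray(centers_theta)[order]
    hs = halfang[order]
    for i in range(len(cs)):
        jn = (i + 1) % len(cs)
        gap = (cs[jn] - cs[i]) % (2 * np.pi)
        if hs[i] + hs[jn] >= gap:
            raise MeshError("electrode arcs overlap; reduce width or count")
    for c, h in zip(centers_theta, halfang):
        d = np.abs(np.angle(np.exp(1j * (ang - c))))
        sel = np.where(d <= h)[0]
        if sel.size == 0:
            raise MeshError("electrode captured no boundary edges; refine mesh")
        patches.append(bedges[sel])
    return patches


# ---------------------------------------------------------------------------
# 3D layered-ball meshes
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ]
    )


def ball_mesh_3d(radius: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Tetrahedral mesh of a ball via Delaunay of radial shells.

    Shell spacing ``h`` (cm); each shell carries ~4*pi*r^2/h^2 Fibonacci
    points.  Interior shell radii are deterministically jittered to avoid
    cospherical degeneracies in the Delaunay step.
    """
    n_shell = max(2, int(round(radius / h)))
    pts = [np.zeros((1, 3))]
    rng = np.random.default_rng(12345)  # fixed: mesh is a deterministic object
    for k in range(1, n_shell + 1):
        r = radius * k / n_shell
        n = max(6, int(round(4 * np.pi * r**2 / h**2)))
        sph = _fibonacci_sphere(n)
        rr = np.full(n, r)
        if k < n_shell:
            rr += 1e-3 * h * (rng.random(n) - 0.5)
        pts.append(sph * rr[:, None])
    pts = np.concatenate(pts, axis=0)
    tri = Delaunay(pts)
    # drop sliver tets of negligible measure (can appear on the hull)
    meas = _simplex_measures(pts, tri.simplices)
    keep = meas > 1e-9 * np.median(meas)
    return pts, tri.simplices[keep]


def assign_electrodes_3d(nodes, simplices, directions, diameter_cm) -> list:
    """Boundary triangles whose centroid lies within the spherical cap of
    angular radius (diameter/2)/R around each electrode direction."""
    bfaces = _boundary_facets(simplices, 3)
    cents = nodes[bfaces].mean(axis=1)
    rad = np.linalg.norm(cents, axis=1)
    cdir = cents / rad[:, None]
    R = float(np.max(np.linalg.norm(nodes, axis=1)))
    cap = (diameter_cm / 2.0) / R
    dirs = np.asarray(directions, dtype=float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    dots = cdir @ dirs.T
    best = np.argmax(dots, axis=1)
    angles = np.arccos(np.clip(dots, -1, 1))
    patches = []
    for l in range(dirs.shape[0]):
        sel = np.where((best == l) & (angles[:, l] <= cap))[0]
        if sel.size == 0:
            raise MeshError(
                "electrode %d captured no boundary facets; enlarge diameter "
                "or refine mesh" % l
            )
        patches.append(bfaces[sel])
    return patches


# ---------------------------------------------------------------------------
# Inter-mesh interpolation
# ---------------------------------------------------------------------------

def interpolation_matrix(src: FEMesh, points: np.ndarray):
    """Sparse (n_points, src.n_nodes) piecewise-linear interpolation matrix.

    Evaluates the nodal hat-basis of ``src`` at arbitrary points; points
    outside the mesh fall back to nearest-node injection.
    """
    from scipy import sparse

    points = np.asarray(points, dtype=float)
    d = src.dim
    cents = src.nodes[src.simplices].mean(axis=1)
    tree = cKDTree(cents)
    k = min(32, len(cents))
    _, cand = tree.query(points, k=k)
    if cand.ndim == 1:
        cand = cand[:, None]

    rows, cols, vals = [], [], []
    node_tree = cKDTree(src.nodes)
    for i, p in enumerate(points):
        placed = False
        for e in cand[i]:
            verts = src.simplices[e]
            X = src.nodes[verts]
            T = (X[1:] - X[0]).T
            try:
                lam = np.linalg.solve(T, p - X[0])
            except np.linalg.LinAlgError:
                continue
            bary = np.concatenate([[1 - lam.sum()], lam])
            if np.all(bary >= -1e-9):
                rows.extend([i] * (d + 1))
                cols.extend(verts.tolist())
                vals.extend(np.clip(bary, 0, None).tolist())
                placed = True
                break
        if not placed:
            _, j = node_tree.query(p)
            rows.append(i)
            cols.append(int(j))
            vals.append(1.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(points), src.n_nodes)
    )
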