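"""Complete-electrode-model (CEM) forward solver for EIT.

The electric potential u inside the head satisfies div(sigma grad u) = 0
with the CEM boundary conditions: under electrode l with contact impedance
z_l, u + z_l sigma du/dn = U_l; the integral of the current density over
the electrode equals the injected current I_l; and no current leaves the
boundary between electrodes.  Injected currents and measured electrode
voltages both sum to zero (conservation of charge and the ground choice).

Discretization: piecewise-linear FE basis for u and for the conductivity
sigma = sum_h sigma_h phi_h.  The variational system couples the interior
potential with the L electrode voltages; the zero-mean voltage ground is
enforced with a single Lagrange multiplier, giving a symmetric sparse
system factorized once per conductivity and reused for all current
patterns (and for the adjoint solves of the Jacobian).

Units: node coordinates in cm (converted to metres internally), currents
in mA (converted to A), conductivity S/m, contact impedance Ohm*m^2.
Voltages are returned in volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu

from .mesh import FEMesh, MeshError

CM = 0.01  # cm -> m
MA = 1e-3  # mA -> A


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class CurrentPatternSet:
    """P zero-sum current patterns over L electrodes (amplitudes in mA)."""

    patterns: np.ndarray  # (P, L), mA
    mode: str
    amplitude: float

    @property
    def n_patterns(self):
        return self.patterns.shape[0]

    @property
    def n_electrodes(self):
        return self.patterns.shape[1]


def build_current_patterns(
    L: int, mode: str = "adjacent", amplitude: float = 1.0, pairs=None
) -> CurrentPatternSet:
    """Adjacent patterns (+I on l, -I on l+1 cyclically) or an explicit
    pairwise injection list (default for pairwise: (l, l + L/2 mod L))."""
    if L < 2:
        raise ValueError("need at least two electrodes")
    if mode == "adjacent":
        P = np.zeros((L, L))
        for j in range(L):
            P[j, j] = amplitude
            P[j, (j + 1) % L] = -amplitude
    elif mode == "pairwise":
        if pairs is None:
            pairs = [(j, (j + L // 2) % L) for j in range(L)]
        P = np.zeros((len(pairs), L))
        for j, (a, b) in enumerate(pairs):
            P[j, a] = amplitude
            P[j, b] = -amplitude
    else:
        raise ValueError("unknown current pattern mode: %r" % mode)
    assert np.allclose(P.sum(axis=1), 0.0)
    return CurrentPatternSet(patterns=P, mode=mode, amplitude=amplitude)


@dataclass(frozen=True)
class ElectrodeModel:
    """Per-electrode contact impedances (Ohm*m^2)."""

    contact_impedances: np.ndarray

    def __post_init__(self):
        z = np.atleast_1d(np.asarray(self.contact_impedances, dtype=float))
        if np.any(z <= 0):
            raise ValueError("contact impedances must be positive")
        object.__setattr__(self, "contact_impedances", z)


def uniform_electrodes(L: int, z: float = 1e-3) -> ElectrodeModel:
    return ElectrodeModel(contact_impedances=np.full(L, z))


@dataclass
class VoltageFrame:
    """Electrode voltages for all current patterns.

    voltages: (P, L) volts; each row sums to zero (ground choice).
    noise_std: standard deviation of the additive Gaussian noise (V).
    """

    voltages: np.ndarray
    noise_std: float = 0.0
    pattern_mode: str = "adjacent"

    @property
    def flat(self) -> np.ndarray:
        return self.voltages.ravel()


@dataclass
class LinearizedModel:
    """Best-fit constant conductivity and the voltage Jacobian there."""

    sigma0: float
    jacobian: np.ndarray  # (P*L, N_inverse) in V per (S/m)
    mesh: FEMesh = None


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _element_geometry(mesh: FEMesh):
    """Per-element gradient operators and measures, in SI units; cached."""
    if "fem_geom" in mesh._cache:
        return mesh._cache["fem_geom"]
    d = mesh.dim
    X = mesh.nodes[mesh.simplices] * CM  # (E, d+1, d) metres
    V = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)  # (E, d, d)
    Vinv = np.linalg.inv(V)
    # gradients of barycentric coordinates: lambda_k, k=1..d rows of Vinv^T?
    # grad lambda_k (k>=1) are rows of Vinv; grad lambda_0 = -sum
    G = np.empty((X.shape[0], d + 1, d))
    G[:, 1:, :] = np.swapaxes(Vinv, 1, 2)
    G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
    det = np.abs(np.linalg.det(V))
    meas = det / (2.0 if d == 2 else 6.0)
    mesh._cache["fem_geom"] = (G, meas)
    return G, meas


def _facet_measures(mesh: FEMesh, facets: np.ndarray):
    X = mesh.nodes[facets] * CM
    if mesh.dim == 2:
        return np.linalg.norm(X[:, 1] - X[:, 0], axis=1)
    a = X[:, 1] - X[:, 0]
    b = X[:, 2] - X[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _electrode_blocks(mesh: FEMesh, electrodes: ElectrodeModel):
    """sigma-independent CEM boundary terms; cached per (mesh, z)."""
    key = ("cem_blocks", tuple(electrodes.contact_impedances))
    if key in mesh._cache:
        return mesh._cache[key]
    N = mesh.n_nodes
    L = mesh.n_electrodes
    d = mesh.dim
    rows, cols, vals = [], [], []
    Cmat = np.zeros((N, L))
    areas = np.zeros(L)
    if d == 2:
        Mref = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
        phi_int = np.array([0.5, 0.5])
    else:
        Mref = (np.ones((3, 3)) + np.eye(3)) / 12.0
        phi_int = np.array([1.0, 1.0, 1.0]) / 3.0
    for l, facets in enumerate(mesh.electrode_patches):
        z = electrodes.contact_impedances[l]
        fm = _facet_measures(mesh, facets)
        areas[l] = fm.sum()
        for k in range(d):
            for m in range(d):
                rows.extend(facets[:, k].tolist())
                cols.extend(facets[:, m].tolist())
                vals.extend((fm * Mref[k, m] / z).tolist())
            np.add.at(Cmat[:, l], facets[:, k], -fm * phi_int[k] / z)
    Z = sparse.csr_matrix((vals, (rows, cols)), shape=(N, N))
    G = np.diag(areas / electrodes.contact_impedances)
    mesh._cache[key] = (Z, Cmat, G)
    return Z, Cmat, G


def _stiffness(mesh: FEMesh, sigma: np.ndarray):
    G, meas = _element_geometry(mesh)
    sig_e = sigma[mesh.simplices].mean(axis=1)
    # element stiffness: sigma_e * |T| * G G^T
    Ke = np.einsum("e,e,ead,ebd->eab", sig_e, meas, G, G)
    d1 = mesh.dim + 1
    rows = np.repeat(mesh.simplices, d1, axis=1).ravel()
    cols = np.tile(mesh.simplices, (1, d1)).ravel()
    return sparse.csr_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )


class CEMSystem:
    """Assembled CEM system for one mesh + electrode model + conductivity.

    Unknowns: N interior nodal potentials, L electrode voltages, and one
    Lagrange multiplier enforcing sum(U) = 0 (which also grounds the
    otherwise floating potential).
    """

    def __init__(self, mesh: FEMesh, sigma, electrodes: ElectrodeModel):
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (mesh.n_nodes,))
        if np.any(sigma <= 0):
            raise SolverError("conductivity must be strictly positive")
        if mesh.n_electrodes == 0:
            raise MeshError("mesh has no electrode patches")
        self.mesh = mesh
        N, L = mesh.n_nodes, mesh.n_electrodes
        A = _stiffness(mesh, sigma)
        Z, C, Gd = _electrode_blocks(mesh, electrodes)
        one = np.ones((L, 1))
        K = sparse.bmat(
            [
                [A + Z, sparse.csr_matrix(C), None],
                [sparse.csr_matrix(C.T), sparse.csr_matrix(Gd), one],
                [None, one.T, None],
            ],
            format="csc",
        )
        try:
            self.lu = splu(K)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise SolverError("CEM system factorization failed: %s" % exc)
        self.N, self.L = N, L

    def solve(self, patterns: CurrentPatternSet):
        """Solutions for all patterns: (fields (N,P), voltages (P,L))."""
        P = patterns.n_patterns
        rhs = np.zeros((self.N + self.L + 1, P))
        rhs[self.N : self.N + self.L, :] = patterns.patterns.T * MA
        x = self.lu.solve(rhs)
        return x[: self.N], x[self.N : self.N + self.L].T

    def solve_adjoint_measurements(self):
        """Fields of the L adjoint problems (unit load on each electrode
        voltage equation); used by the adjoint Jacobian."""
        rhs = np.zeros((self.N + self.L + 1, self.L))
        rhs[self.N : self.N + self.L, :] = np.eye(self.L)
        x = self.lu.solve(rhs)
        return x[: self.N]


def solve_forward(
    mesh: FEMesh,
    sigma,
    electrodes: ElectrodeModel,
    patterns: CurrentPatternSet,
) -> VoltageFrame:
    """Noiseless CEM electrode voltages for all current patterns."""
    if patterns.n_electrodes != mesh.n_electrodes:
        raise MeshError("pattern electrode count does not match mesh")
    sys = CEMSystem(mesh, sigma, electrodes)
    _, U = sys.solve(patterns)
    return VoltageFrame(voltages=U, noise_std=0.0, pattern_mode=patterns.mode)


def add_noise(
    frame: VoltageFrame,
    noise_fraction: float,
    reference_amplitude: float,
    rng: np.random.Generator,
) -> VoltageFrame:
    """Additive i.i.d. Gaussian noise, std = fraction * reference amplitude."""
    if noise_fraction < 0:
        raise ValueError("noise fraction must be nonnegative")
    if noise_fraction == 0:
        return replace(frame)
    std = noise_fraction * reference_amplitude
    noisy = frame.voltages + rng.normal(0.0, std, size=frame.voltages.shape)
    return VoltageFrame(
        voltages=noisy, noise_std=std, pattern_mode=frame.pattern_mode
    )


# ---------------------------------------------------------------------------
# Jacobian and linearization point
# ---------------------------------------------------------------------------

def compute_jacobian(
    forward_mesh: FEMesh,
    inverse_mesh: FEMesh,
    sigma0: float,
    electrodes: ElectrodeModel,
    patterns: CurrentPatternSet,
) -> LinearizedModel:
    """Sensitivity of all electrode voltages to nodal conductivity.

    Adjoint formulation: dU_l^(j)/dsigma_h = -int phi_h grad(u_j).grad(w_l)
    with u_j the drive fields and w_l the measurement adjoint fields, both
    solved on ``forward_mesh`` at the constant sigma0.  If the inverse mesh
    differs, the sensitivity is chained through piecewise-linear
    interpolation of the inverse-mesh basis onto the forward-mesh nodes.
    """
    sys = CEMSystem(forward_mesh, sigma0, electrodes)
    u, _ = sys.solve(patterns)                   # (N, P)
    w = sys.solve_adjoint_measurements()         # (N, L)
    G, meas = _element_geometry(forward_mesh)
    simp = forward_mesh.simplices
    d1 = forward_mesh.dim + 1
    # element-constant gradients of all fields
    gu = np.einsum("ead,eap->edp", G, u[simp])   # (E, d, P)
    gw = np.einsum("ead,eal->edl", G, w[simp])   # (E, d, L)
    P, L = patterns.n_patterns, patterns.n_electrodes
    J = np.zeros((P * L, forward_mesh.n_nodes))
    chunk = max(1, int(2e7 // (gu.shape[0] * L)))
    for p0 in range(0, P, chunk):
        p1 = min(P, p0 + chunk)
        S = np.einsum("edp,edl->epl", gu[:, :, p0:p1], gw)  # (E, p, L)
        S *= -(meas / d1)[:, None, None]
        S = S.reshape(gu.shape[0], -1)  # (E, p*L)
        for k in range(d1):
            np.add.at(J.T[:, p0 * L : p1 * L], simp[:, k], S)
    if inverse_mesh is not forward_mesh:
        from .mesh import interpolation_matrix

        Pmat = interpolation_matrix(inverse_mesh, forward_mesh.nodes)
        J = J @ Pmat.toarray() if Pmat.shape[1] < 4000 else J @ Pmat
        J = np.asarray(J)
    return LinearizedModel(sigma0=float(sigma0), jacobian=J, mesh=inverse_mesh)


def fit_constant_sigma0(
    V1: VoltageFrame,
    mesh: FEMesh,
    electrodes: ElectrodeModel,
    patterns: CurrentPatternSet,
    bounds=(1e-3, 3.0),
    xatol=1e-6,
) -> float:
    """Best-fitting spatially constant conductivity for frame V1.

    Minimizes ||V1 - U(s * 1)||^2 over s by bounded 1D search on log s.
    """
    target = V1.voltages

    def objective(logs):
        sys = CEMSystem(mesh, np.exp(logs), electrodes)
        _, U = sys.solve(patterns)
        return float(np.sum((U - target) ** 2))

    res = minimize_scalar(
        objective,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": xatol, "maxiter": 60},
    )
    if not res.success:  # pragma: no cover
        raise SolverError("sigma0 fit did not converge: %s" % res.message)
    return float(np.exp(res.x))
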