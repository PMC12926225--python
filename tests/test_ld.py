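import numpy as np
import pytest

from eitgraph.fem import compute_jacobian, solve_forward
from eitgraph.ld import build_correlation_prior, reconstruct_ld
from eitgraph.metrics import half_max_region
from eitgraph.phantoms import HemorrhagePair, render_conductivity


@pytest.fixture(scope="module")
def prior(disc_mesh):
    return build_correlation_prior(disc_mesh, correlation_length=6.0)


@pytest.fixture(scope="module")
def lin(disc_mesh, setup2d):
    el, pat = setup2d
    return compute_jacobian(disc_mesh, disc_mesh, 0.0695, el, pat)


def _frames(mesh, sigma1, sigma2, el, pat, std=1e-5):
    V1 = solve_forward(mesh, sigma1, el, pat)
    V2 = solve_forward(mesh, sigma2, el, pat)
    V1.noise_std = std
    V2.noise_std = std
    return V1, V2


def test_prior_diagonal_and_monotonicity(disc_mesh, prior):
    RtR = prior.R.T @ prior.R
    Gamma = np.linalg.inv(RtR)
    vs = prior.variance_scale
    assert np.allclose(np.diag(Gamma), vs * (1 + 1e-6), rtol=1e-4)
    # entries decay with distance from node 0
    d = np.linalg.norm(disc_mesh.nodes - disc_mesh.nodes[0], axis=1)
    order = np.argsort(d)
    row = Gamma[0, order]
    # non-increasing with distance (ties between equidistant nodes allowed)
    assert np.all(np.diff(row) < 1e-8 * vs)


def test_prior_factor_inverts_covariance(disc_mesh, prior):
    """R^T R is the inverse of the stated covariance kernel."""
    from scipy.spatial.distance import cdist

    x = disc_mesh.nodes
    b = prior.correlation_length / np.sqrt(2 * np.log(100))
    Gamma = prior.variance_scale * np.exp(
        -cdist(x, x, "sqeuclidean") / (2 * b**2)
    )
    Gamma[np.diag_indices_from(Gamma)] += 1e-6 * prior.variance_scale
    prod = prior.R.T @ prior.R @ Gamma
    assert np.abs(prod - np.eye(len(x))).max() < 1e-6


def test_zero_data_difference_gives_zero_image(disc_mesh, setup2d, lin, prior):
    el, pat = setup2d
    sigma = np.full(disc_mesh.n_nodes, 0.0695)
    V1, V2 = _frames(disc_mesh, sigma, sigma, el, pat)
    img = reconstruct_ld(V1, V1, lin, prior)
    assert np.allclose(img.values, 0.0)


def test_linearity_in_data(disc_mesh, setup2d, lin, prior):
    el, pat = setup2d
    base = np.full(disc_mesh.n_nodes, 0.0695)
    bumps = []
    for cx in (2.0, -3.0):
        s = base.copy()
        s[np.linalg.norm(disc_mesh.nodes - [cx, 1.0], axis=1) < 2.5] = 0.1
        bumps.append(s)
    V1, V2 = _frames(disc_mesh, base, bumps[0], el, pat)
    _, V3 = _frames(disc_mesh, base, bumps[1], el, pat)
    d12 = reconstruct_ld(V1, V2, lin, prior).values
    d23 = reconstruct_ld(V2, V3, lin, prior).values
    d13 = reconstruct_ld(V1, V3, lin, prior).values
    assert np.allclose(d12 + d23, d13, atol=1e-10)


def test_normal_equation_residual(disc_mesh, setup2d, lin, prior):
    el, pat = setup2d
    base = np.full(disc_mesh.n_nodes, 0.0695)
    s2 = base.copy()
    s2[np.linalg.norm(disc_mesh.nodes - [3.0, 0.0], axis=1) < 2.0] = 0.3
    V1, V2 = _frames(disc_mesh, base, s2, el, pat)
    img = reconstruct_ld(V1, V2, lin, prior)
    var = V1.noise_std**2 + V2.noise_std**2
    J = lin.jacobian
    H = J.T @ J / var + prior.R.T @ prior.R
    g = J.T @ (V2.voltages - V1.voltages).ravel() / var
    resid = np.linalg.norm(H @ img.values - g)
    assert resid < 1e-8 * np.linalg.norm(g)


def test_zero_noise_metadata_uses_floor(disc_mesh, setup2d, lin, prior):
    el, pat = setup2d
    base = np.full(disc_mesh.n_nodes, 0.0695)
    s2 = base.copy()
    s2[np.linalg.norm(disc_mesh.nodes - [3.0, 0.0], axis=1) < 2.0] = 0.3
    V1 = solve_forward(disc_mesh, base, el, pat)
    V2 = solve_forward(disc_mesh, s2, el, pat)
    with pytest.warns(UserWarning):
        img = reconstruct_ld(V1, V2, lin, prior)
    assert np.all(np.isfinite(img.values))


def test_weaker_prior_does_not_increase_misfit(disc_mesh, setup2d, lin):
    el, pat = setup2d
    base = np.full(disc_mesh.n_nodes, 0.0695)
    s2 = base.copy()
    s2[np.linalg.norm(disc_mesh.nodes - [2.0, 2.0], axis=1) < 2.0] = 0.3
    V1, V2 = _frames(disc_mesh, base, s2, el, pat)
    dV = (V2.voltages - V1.voltages).ravel()
    misfits = []
    for vs in (0.01**2, 0.1**2, 1.0**2):
        prior = build_correlation_prior(disc_mesh, 6.0, variance_scale=vs)
        img = reconstruct_ld(V1, V2, lin, prior)
        misfits.append(np.linalg.norm(dV - lin.jacobian @ img.values))
    assert misfits[0] >= misfits[1] >= misfits[2]


def test_localization_of_single_inclusion(
    geom2d, disc_mesh, disc_mesh_fine, setup2d, prior
):
    """A 2 cm conductivity increase is reconstructed within 2 cm of its
    true location (data from a finer mesh than the inversion mesh)."""
    el, pat = setup2d
    center = (3.0, 0.5)
    nothing = HemorrhagePair(center=center, radius=0.0, direction=(1.0, 0.0),
                             axis_length=2.0)
    bleed = HemorrhagePair(center=center, radius=2.0, direction=(1.0, 0.0),
                           axis_length=2.0)
    s1 = render_conductivity(geom2d, nothing, "initial", disc_mesh_fine)
    s2 = render_conductivity(geom2d, bleed, "initial", disc_mesh_fine)
    V1, V2 = _frames(disc_mesh_fine, s1, s2, el, pat)
    lin = compute_jacobian(disc_mesh, disc_mesh, 0.05, el, pat)
    img = reconstruct_ld(V1, V2, lin, prior)
    ind, _ = half_max_region(img.values, disc_mesh)
    w = disc_mesh.nodal_volumes()[ind]
    cm = (w[:, None] * disc_mesh.nodes[ind]).sum(axis=0) / w.sum()
    assert np.linalg.norm(cm - center) < 2.0
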