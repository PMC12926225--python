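import numpy as np
import pytest

from eitgraph.fem import (
    VoltageFrame,
    add_noise,
    build_current_patterns,
    compute_jacobian,
    fit_constant_sigma0,
    solve_forward,
    uniform_electrodes,
)
from eitgraph.fixtures import disc_meshes


def test_current_patterns():
    adj = build_current_patterns(16, "adjacent", 1.0)
    assert adj.patterns.shape == (16, 16)
    assert np.allclose(adj.patterns.sum(axis=1), 0.0)
    two = build_current_patterns(2, "adjacent", 1.0)
    assert np.allclose(two.patterns, [[1, -1], [-1, 1]])
    pw = build_current_patterns(32, "pairwise", 1.0)
    assert pw.patterns.shape == (32, 32)
    assert np.allclose(np.abs(pw.patterns).sum(axis=1), 2.0)
    with pytest.raises(ValueError):
        build_current_patterns(16, "spiral", 1.0)


def test_ground_condition(disc_mesh, setup2d):
    el, pat = setup2d
    f = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, 0.2), el, pat)
    sums = np.abs(f.voltages.sum(axis=1))
    assert sums.max() < 1e-10 * np.abs(f.voltages).max()


def test_reciprocity(disc_mesh, setup2d):
    """I_k . U^(j) == I_j . U^(k) for any zero-sum patterns."""
    el, pat = setup2d
    f = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, 0.13), el, pat)
    M = pat.patterns @ f.voltages.T
    assert np.abs(M - M.T).max() < 1e-8 * np.abs(M).max()


def test_self_convergence_under_refinement(setup2d):
    el, pat = setup2d
    Us = []
    for m in disc_meshes((8, 12, 18)):
        f = solve_forward(m, np.full(m.n_nodes, 0.2), el, pat)
        Us.append(f.voltages)
    diffs = [np.abs(Us[i + 1] - Us[i]).max() for i in range(2)]
    assert diffs[1] < diffs[0]


def test_contact_impedance_monotonicity(disc_mesh, setup2d):
    _, pat = setup2d
    sigma = np.full(disc_mesh.n_nodes, 0.2)
    lo = solve_forward(disc_mesh, sigma, uniform_electrodes(16, 1e-4), pat)
    hi = solve_forward(disc_mesh, sigma, uniform_electrodes(16, 1e-2), pat)
    driven_lo = np.abs(np.diag(lo.voltages))
    driven_hi = np.abs(np.diag(hi.voltages))
    assert np.all(driven_hi > driven_lo)


def test_add_noise_statistics(rng):
    clean = VoltageFrame(voltages=np.zeros((500, 200)))
    noisy = add_noise(clean, 0.00067, 1.0, rng)
    resid = noisy.voltages - clean.voltages
    assert abs(resid.std() / 0.00067 - 1.0) < 0.02
    assert noisy.noise_std == pytest.approx(0.00067)
    same = add_noise(clean, 0.0, 1.0, rng)
    assert np.array_equal(same.voltages, clean.voltages)
    with pytest.raises(ValueError):
        add_noise(clean, -0.1, 1.0, rng)


def test_jacobian_matches_finite_differences(disc_mesh, setup2d):
    el, pat = setup2d
    s0 = 0.2
    lin = compute_jacobian(disc_mesh, disc_mesh, s0, el, pat)
    eps = 1e-4 * s0
    U0 = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, s0), el, pat)
    U1 = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, s0 + eps), el, pat)
    fd = (U1.voltages - U0.voltages).ravel()
    pred = lin.jacobian @ np.full(disc_mesh.n_nodes, eps)
    assert np.linalg.norm(pred - fd) < 1e-3 * np.linalg.norm(fd)


def test_boundary_sensitivity_exceeds_central(disc_mesh, setup2d):
    el, pat = setup2d
    lin = compute_jacobian(disc_mesh, disc_mesh, 0.2, el, pat)
    col_norm = np.linalg.norm(lin.jacobian, axis=0)
    r = np.linalg.norm(disc_mesh.nodes, axis=1)
    central = np.argmin(r)
    near_electrode = disc_mesh.electrode_patches[0][0][0]
    assert col_norm[near_electrode] > col_norm[central]


def test_jacobian_across_meshes(disc_mesh, disc_mesh_fine, setup2d):
    """Chaining through inter-mesh interpolation matches a direct solve."""
    el, pat = setup2d
    lin = compute_jacobian(disc_mesh_fine, disc_mesh, 0.2, el, pat)
    assert lin.jacobian.shape == (256, disc_mesh.n_nodes)
    eps = 1e-4 * 0.2
    U0 = solve_forward(
        disc_mesh_fine, np.full(disc_mesh_fine.n_nodes, 0.2), el, pat
    )
    U1 = solve_forward(
        disc_mesh_fine, np.full(disc_mesh_fine.n_nodes, 0.2 + eps), el, pat
    )
    fd = (U1.voltages - U0.voltages).ravel()
    pred = lin.jacobian @ np.full(disc_mesh.n_nodes, eps)
    assert np.linalg.norm(pred - fd) < 1e-3 * np.linalg.norm(fd)


def test_fit_constant_sigma0_exact_recovery(disc_mesh, setup2d):
    el, pat = setup2d
    truth = 0.2
    V1 = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, truth), el, pat)
    fit = fit_constant_sigma0(V1, disc_mesh, el, pat)
    assert abs(fit - truth) < 1e-4 * truth


def test_fit_constant_sigma0_scaling(disc_mesh, setup2d):
    """With negligible contact impedance, scaling voltages by 2 halves the
    fitted conductivity (U ~ 1/sigma at fixed current)."""
    _, pat = setup2d
    el = uniform_electrodes(16, 1e-9)
    V1 = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, 0.2), el, pat)
    doubled = VoltageFrame(voltages=2.0 * V1.voltages)
    fit = fit_constant_sigma0(doubled, disc_mesh, el, pat)
    assert fit == pytest.approx(0.1, rel=1e-3)


def test_fit_constant_sigma0_with_noise(disc_mesh, setup2d, rng):
    el, pat = setup2d
    truth = 0.2
    V1 = solve_forward(disc_mesh, np.full(disc_mesh.n_nodes, truth), el, pat)
    noisy = add_noise(V1, 0.00067, np.abs(V1.voltages).max(), rng)
    fit = fit_constant_sigma0(noisy, disc_mesh, el, pat)
    assert abs(fit - truth) < 0.01 * truth
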