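import numpy as np
import pytest

from eitgraph.graphs import (
    build_cluster_hierarchy,
    mesh_to_graph,
    permute_graph,
    permute_hierarchy,
)
from eitgraph.nets import (
    Adam,
    GraphUNet,
    GResNet,
    _pool_max,
    _sp_apply,
    _unpool_clone,
    normalized_apply,
)
from eitgraph.phantoms import build_head_geometry, build_mesh


@pytest.fixture(scope="module")
def small_setup():
    geom = build_head_geometry(2)
    mesh = build_mesh(geom, 5)
    g = mesh_to_graph(mesh)
    h = build_cluster_hierarchy(g, levels=3, seed=0)
    return g, h


@pytest.fixture(scope="module")
def tet_setup():
    geom = build_head_geometry(3)
    mesh = build_mesh(geom, 4)
    g = mesh_to_graph(mesh)
    h = build_cluster_hierarchy(g, levels=3, seed=0)
    return g, h


def test_default_parameter_count_near_327k():
    n = GraphUNet().n_parameters
    assert abs(n - 327_000) <= 0.02 * 327_000


def test_minimal_network_has_two_parameters():
    assert GraphUNet(channels=(1,), convs_per_level=0).n_parameters == 2


def test_parameter_count_independent_of_graph(small_setup, tet_setup):
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=2)
    n0 = net.n_parameters
    for g, h in (small_setup, tet_setup):
        net.forward(g, h, np.zeros((1, g.n_nodes, 1)))
    assert net.n_parameters == n0


def test_propagation_rule_on_path_graph():
    from scipy import sparse

    from eitgraph.graphs import graph_from_adjacency

    A = sparse.csr_matrix(
        ([1.0, 1, 1, 1], ([0, 1, 1, 2], [1, 0, 2, 1])), shape=(3, 3)
    )
    g = graph_from_adjacency(A, np.zeros((3, 2)))
    H = np.array([[[1.0], [0.0], [0.0]]])
    out = _sp_apply(g.normalizer, H)
    assert out[0, :, 0] == pytest.approx([0.5, 1 / np.sqrt(6), 0.0])


def test_gcn_propagate_contract():
    from scipy import sparse

    from eitgraph.graphs import graph_from_adjacency
    from eitgraph.nets import gcn_propagate

    # no edges: normalizer is the identity, so W=I, bias=0 passes through
    g = graph_from_adjacency(sparse.csr_matrix((3, 3)), np.zeros((3, 2)))
    H = np.array([[1.0, -2.0], [0.5, 0.0], [-1.0, 3.0]])
    out = gcn_propagate(g, H, np.eye(2), activation=False)
    assert np.allclose(out, H)
    # rectification when activation is on
    assert np.allclose(gcn_propagate(g, H, np.eye(2)), np.maximum(H, 0))
    with pytest.raises(ValueError):
        gcn_propagate(g, H, np.eye(3))


def test_pool_unpool_algebra():
    assign = np.array([0, 0, 1])
    H = np.array([[[3.0], [5.0], [2.0]]])
    pooled = _pool_max(assign, H, 2)
    assert pooled[0, :, 0] == pytest.approx([5.0, 2.0])
    cloned = _unpool_clone(assign, pooled)
    assert cloned[0, :, 0] == pytest.approx([5.0, 5.0, 2.0])
    # pool o unpool = identity on coarse signals
    assert np.allclose(_pool_max(assign, cloned, 2), pooled)
    # unpool o pool is a projection
    once = _unpool_clone(assign, _pool_max(assign, H, 2))
    twice = _unpool_clone(assign, _pool_max(assign, once, 2))
    assert np.allclose(once, twice)


def test_zero_input_zero_bias_gives_zero_output(small_setup):
    g, h = small_setup
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=2, seed=3)
    X = np.zeros((2, g.n_nodes, 1))
    assert np.allclose(net.forward(g, h, X), 0.0)


def test_forward_is_permutation_equivariant(small_setup, rng):
    g, h = small_setup
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=2, seed=1)
    x = rng.normal(size=(1, g.n_nodes, 1))
    out = net.forward(g, h, x)
    perm = rng.permutation(g.n_nodes)
    gp = permute_graph(g, perm)
    hp = permute_hierarchy(h, perm)
    xp = np.empty_like(x)
    xp[0, perm, 0] = x[0, :, 0]
    outp = net.forward(gp, hp, xp)
    assert np.allclose(outp[0, perm, 0], out[0, :, 0], atol=1e-10)


def test_gradients_match_finite_differences(small_setup):
    g, h = small_setup
    rng = np.random.default_rng(0)
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=3, seed=1)
    # move weights off the exact ReLU kinks of the zero-bias init
    v0 = net.get_flat() + 0.05 * rng.normal(size=net.n_parameters)
    net.set_flat(v0)
    X = rng.normal(size=(2, g.n_nodes, 1))
    T = rng.normal(size=(2, g.n_nodes, 1))
    out, back = net.forward(g, h, X, train=True)
    grads = back(out - T)
    ga = np.concatenate([np.concatenate([W.ravel(), b]) for W, b in grads])
    d = rng.normal(size=v0.size)
    d /= np.linalg.norm(d)
    eps = 1e-6

    def loss(v):
        net.set_flat(v)
        return 0.5 * np.sum((net.forward(g, h, X) - T) ** 2)

    fd = (loss(v0 + eps * d) - loss(v0 - eps * d)) / (2 * eps)
    net.set_flat(v0)
    assert abs(fd - ga @ d) < 1e-4 * abs(fd)


def test_same_parameters_run_on_2d_and_3d_graphs(small_setup, tet_setup):
    net = GraphUNet(seed=0)
    for g, h in (small_setup, tet_setup):
        out = net.forward(g, h, np.ones((1, g.n_nodes, 1)))
        assert out.shape == (1, g.n_nodes, 1)
        assert np.all(np.isfinite(out))


def test_hierarchy_graph_mismatch_raises(small_setup, tet_setup):
    g2, _ = small_setup
    _, h3 = tet_setup
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=1)
    with pytest.raises(ValueError):
        net.forward(g2, h3, np.zeros((1, g2.n_nodes, 1)))


def test_gresnet_structure_and_identity(small_setup):
    g, h = small_setup
    net = GResNet()
    assert net.blocks == 10 and net.convs_per_block == 3
    assert len(net.weights) == 1 + 10 * 3 + 1
    net.set_flat(np.zeros(net.n_parameters))
    x = np.random.default_rng(0).normal(size=(1, g.n_nodes, 1))
    assert np.allclose(net.forward(g, h, x), x)


def test_gresnet_gradients(small_setup, rng):
    g, h = small_setup
    net = GResNet(channels=4, blocks=2, convs_per_block=3, seed=2)
    v0 = net.get_flat() + 0.05 * rng.normal(size=net.n_parameters)
    net.set_flat(v0)
    X = rng.normal(size=(1, g.n_nodes, 1))
    T = rng.normal(size=(1, g.n_nodes, 1))
    out, back = net.forward(g, h, X, train=True)
    ga = np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in back(out - T)]
    )
    d = rng.normal(size=v0.size)
    d /= np.linalg.norm(d)
    eps = 1e-6

    def loss(v):
        net.set_flat(v)
        return 0.5 * np.sum((net.forward(g, h, X) - T) ** 2)

    fd = (loss(v0 + eps * d) - loss(v0 - eps * d)) / (2 * eps)
    net.set_flat(v0)
    assert abs(fd - ga @ d) < 1e-6 * abs(fd)


def test_normalized_apply_scale_equivariance(small_setup, rng):
    g, h = small_setup
    net = GraphUNet(channels=(4, 6, 8, 10), convs_per_level=2, seed=5)
    x = rng.normal(size=g.n_nodes)
    y = normalized_apply(net, g, h, x)
    y2 = normalized_apply(net, g, h, 3.7 * x)
    assert np.allclose(y2, 3.7 * y, atol=1e-12)


def test_adam_reduces_loss(small_setup, rng):
    g, h = small_setup
    net = GraphUNet(channels=(4, 6), convs_per_level=2, seed=7)
    X = rng.normal(size=(2, g.n_nodes, 1))
    # smooth, reachable target (the convolutions are smoothing operators)
    T = 0.5 * _sp_apply(g.normalizer, _sp_apply(g.normalizer, X))
    opt = Adam(net, lr=1e-2)
    losses = []
    for _ in range(80):
        out, back = net.forward(g, h, X, train=True)
        losses.append(float(np.mean((out - T) ** 2)))
        opt.step(back(2 * (out - T) / out.size))
    assert losses[-1] < 0.5 * losses[0]
    assert np.mean(losses[-10:]) < np.mean(losses[:10])
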