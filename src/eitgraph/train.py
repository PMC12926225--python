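"""Dataset assembly, supervised training, and batch evaluation.

``make_training_set`` runs the full simulation pipeline per phantom pair:
sample a hemorrhage pair, render both conductivity frames on a fine
simulation mesh, solve the CEM forward problem, add measurement noise
(std = 0.067% of the dataset's maximum noiseless amplitude by default),
fit the constant linearization point to the first frame, evaluate the
Jacobian on the coarser inverse mesh, and reconstruct the LD difference
image.  The training target is the analytic true conductivity change
rendered at the inverse-mesh nodes.  The simulation and inverse meshes
differ deliberately so reconstructions are never tested against data
produced by the identical discretization.

``train_network`` minimizes the mean squared nodal error between network
outputs and targets (Adam, early stopping on validation loss with
patience, best-validation weights restored).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .fem import (
    CurrentPatternSet,
    ElectrodeModel,
    add_noise,
    build_current_patterns,
    compute_jacobian,
    fit_constant_sigma0,
    solve_forward,
    uniform_electrodes,
)
from .graphs import ClusterHierarchy, GraphStructure, build_cluster_hierarchy, mesh_to_graph
from .ld import build_correlation_prior, reconstruct_ld
from .mesh import FEMesh
from .nets import Adam, normalized_apply
from .phantoms import (
    HeadGeometry,
    build_head_geometry,
    build_mesh,
    render_conductivity,
    sample_hemorrhage_pair,
    true_difference,
)

DEFAULT_NOISE_FRACTION = 6.7e-4  # noise std / max noiseless amplitude


@dataclass
class TrainingSample:
    """LD input image, ground-truth change, and phantom metadata."""

    ld: np.ndarray
    truth: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    patience_epochs: int = 50
    max_epochs: int = 1000
    min_epochs: int = 0   # early stopping cannot trigger before this
    batch_size: int = 8
    full_batch_limit: int = 64
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.max_epochs, self.batch_size) <= 0:
            raise ValueError("training config values must be positive")


@dataclass
class SimulationContext:
    """Everything shared across samples of one dataset."""

    geometry: HeadGeometry
    sim_mesh: FEMesh
    inv_mesh: FEMesh
    electrodes: ElectrodeModel
    patterns: CurrentPatternSet
    prior: object
    graph: GraphStructure = None
    hierarchy: ClusterHierarchy = None


def make_context(
    dimension: int = 2,
    sim_resolution: int = 24,
    inv_resolution: int = 16,
    contact_impedance: float = 1e-3,
    variance_scale: float = 0.1**2,
    cluster_seed: int = 0,
    **geometry_config,
) -> SimulationContext:
    geom = build_head_geometry(dimension, **geometry_config)
    sim_mesh = build_mesh(geom, sim_resolution)
    inv_mesh = build_mesh(geom, inv_resolution)
    electrodes = uniform_electrodes(geom.n_electrodes, contact_impedance)
    mode = "adjacent" if dimension == 2 else "pairwise"
    patterns = build_current_patterns(geom.n_electrodes, mode, amplitude=1.0)
    prior = build_correlation_prior(
        inv_mesh, correlation_length=geom.width / 3.0,
        variance_scale=variance_scale,
    )
    graph = mesh_to_graph(inv_mesh)
    hierarchy = build_cluster_hierarchy(graph, levels=3, seed=cluster_seed)
    return SimulationContext(
        geometry=geom,
        sim_mesh=sim_mesh,
        inv_mesh=inv_mesh,
        electrodes=electrodes,
        patterns=patterns,
        prior=prior,
        graph=graph,
        hierarchy=hierarchy,
    )


def make_training_set(
    n_pairs: int,
    ctx: SimulationContext,
    rng: np.random.Generator,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
) -> list:
    """Simulate ``n_pairs`` phantom pairs and their LD reconstructions."""
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    pairs, clean = [], []
    for i in range(n_pairs):
        try:
            pair = sample_hemorrhage_pair(ctx.geometry, rng)
            s1 = render_conductivity(ctx.geometry, pair, "initial", ctx.sim_mesh)
            s2 = render_conductivity(ctx.geometry, pair, "expanded", ctx.sim_mesh)
            U1 = solve_forward(ctx.sim_mesh, s1, ctx.electrodes, ctx.patterns)
            U2 = solve_forward(ctx.sim_mesh, s2, ctx.electrodes, ctx.patterns)
        except Exception as exc:
            raise RuntimeError("sample %d failed: %s" % (i, exc)) from exc
        pairs.append(pair)
        clean.append((U1, U2))
    ref_amp = max(
        np.max(np.abs(f.voltages)) for fr in clean for f in fr
    )
    samples = []
    for i, (pair, (U1, U2)) in enumerate(zip(pairs, clean)):
        V1 = add_noise(U1, noise_fraction, ref_amp, rng)
        V2 = add_noise(U2, noise_fraction, ref_amp, rng)
        sigma0 = fit_constant_sigma0(V1, ctx.inv_mesh, ctx.electrodes, ctx.patterns)
        lin = compute_jacobian(
            ctx.inv_mesh, ctx.inv_mesh, sigma0, ctx.electrodes, ctx.patterns
        )
        img = reconstruct_ld(V1, V2, lin, ctx.prior)
        truth = true_difference(pair, ctx.geometry, ctx.inv_mesh)
        samples.append(
            TrainingSample(
                ld=img.values,
                truth=truth,
                meta=dict(
                    index=i,
                    sigma0=sigma0,
                    radius=pair.radius,
                    axis_length=pair.axis_length,
                    center=pair.center,
                ),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(samples):
    """Stack normalized inputs, targets, and per-sample scales."""
    X = np.stack([s.ld for s in samples])[:, :, None]
    T = np.stack([s.truth for s in samples])[:, :, None]
    scale = np.max(np.abs(X), axis=(1, 2))
    scale[scale == 0] = 1.0
    return X / scale[:, None, None], T, scale


def _loss_and_grad(net, graph, hierarchy, Xn, T, scale, want_grad=True):
    """Mean over samples and nodes of (scale*net(x/scale) - target)^2."""
    if want_grad:
        out, backward = net.forward(graph, hierarchy, Xn, train=True)
    else:
        out = net.forward(graph, hierarchy, Xn)
    y = out * scale[:, None, None]
    resid = y - T
    B, N, _ = Xn.shape
    loss = float(np.mean(resid**2))
    if not want_grad:
        return loss, None
    dOut = 2.0 * resid * scale[:, None, None] / (B * N)
    return loss, backward(dOut)


def validation_loss(net, graph, hierarchy, samples):
    Xn, T, scale = _batch_arrays(samples)
    loss, _ = _loss_and_grad(net, graph, hierarchy, Xn, T, scale, want_grad=False)
    return loss


def train_network(
    net,
    train_samples,
    val_samples,
    graph: GraphStructure,
    hierarchy: ClusterHierarchy,
    config: TrainingConfig = None,
):
    """Adam training with early stopping; returns (net, history).

    The network's weights are updated in place; the best-validation
    weights are restored before returning.  History holds per-epoch train
    and validation losses.
    """
    if not train_samples or not val_samples:
        raise ValueError("need at least one training and one validation sample")
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    opt = Adam(net, lr=config.learning_rate)
    n = len(train_samples)
    full_batch = n <= config.full_batch_limit

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        if full_batch:
            batches = [order]
        else:
            batches = np.array_split(
                order, int(np.ceil(n / config.batch_size))
            )
        ep_loss = 0.0
        for b in batches:
            batch = [train_samples[i] for i in b]
            Xn, T, scale = _batch_arrays(batch)
            loss, grads = _loss_and_grad(net, graph, hierarchy, Xn, T, scale)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged at epoch %d (loss=%r)" % (epoch, loss)
                )
            opt.step(grads)
            ep_loss += loss * len(b)
        history["train_loss"].append(ep_loss / n)
        vloss = validation_loss(net, graph, hierarchy, val_samples)
        history["val_loss"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_weights = copy.deepcopy(net.weights)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience_epochs and epoch + 1 >= config.min_epochs:
                break
    if best_weights is not None:
        net.weights = best_weights
    history["best_val_loss"] = best_val
    return net, history


def evaluate_on_set(
    net, samples, ctx: SimulationContext
) -> pd.DataFrame:
    """Per-sample metrics for LD inputs and network outputs."""
    rows = []
    for s in samples:
        out = (
            normalized_apply(net, ctx.graph, ctx.hierarchy, s.ld)
            if net is not None
            else s.ld
        )
        rec_ld = M.evaluate_image(s.ld, s.truth, ctx.inv_mesh)
        rec_net = M.evaluate_image(out, s.truth, ctx.inv_mesh)
        rows.append(
            {
                "index": s.meta.get("index", -1),
                "mse_ld": rec_ld.mse,
                "mse_net": rec_net.mse,
                "psnr_ld": rec_ld.psnr,
                "psnr_net": rec_net.psnr,
                "cm_error_ld": rec_ld.cm_error,
                "cm_error_net": rec_net.cm_error,
                "volume_error_ld": rec_ld.volume_error,
                "volume_error_net": rec_net.volume_error,
            }
        )
    return pd.DataFrame(rows)
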