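"""Desk-scale end-to-end studies.

The full-scale experiments behind this package (thousands of samples on
meshes with tens of thousands of nodes) are out of reach of a single-CPU
quick run, so these studies reproduce the pipeline at reduced problem
sizes: a ~1.8k-node 2D simulation mesh with a ~0.8k-node inverse mesh,
100/20/20 train/validation/test phantom pairs, and a ~8k/~3.6k-node 3D
layered ball phantom for the dimension-transfer test.  The scientific
claims checked are property-based: the trained graph U-net improves mean
MSE and half-max volume error over its LD inputs, a 20-train/4-validation
network still beats LD, and the 2D-trained network reduces volume error
on 3D reconstructions it has never seen.
"""

from __future__ import annotations

import numpy as np

from .nets import GraphUNet
from .train import (
    SimulationContext,
    TrainingConfig,
    evaluate_on_set,
    make_context,
    make_training_set,
    train_network,
)

STUDY_2D = dict(n_train=100, n_val=20, n_test=20, sim_resolution=24,
                inv_resolution=16)
STUDY_FEWSHOT = dict(n_train=20, n_val=4)
STUDY_3D = dict(n_cases=4, sim_resolution=12, inv_resolution=9)
# With mini-batches on small sample counts an epoch holds few optimizer
# steps, so validation noise at initialization can trigger early stopping
# before any real improvement; require a minimum number of epochs.
STUDY_EPOCHS = dict(max_epochs=300, patience_epochs=50, min_epochs=150,
                    full_batch_limit=1)


def simulate_2d_dataset(seed: int, n_train=100, n_val=20, n_test=20,
                        sim_resolution=24, inv_resolution=16):
    """Simulate the 2D study dataset; returns (ctx, train, val, test)."""
    ctx = make_context(
        2, sim_resolution=sim_resolution, inv_resolution=inv_resolution
    )
    rng = np.random.default_rng(seed)
    n = n_train + n_val + n_test
    samples = make_training_set(n, ctx, rng)
    return (
        ctx,
        samples[:n_train],
        samples[n_train : n_train + n_val],
        samples[n_train + n_val :],
    )


def train_gunet(train_samples, val_samples, ctx: SimulationContext,
                seed: int, **epochs):
    cfg = TrainingConfig(seed=seed, **{**STUDY_EPOCHS, **epochs})
    net = GraphUNet(seed=seed)
    net, history = train_network(
        net, train_samples, val_samples, ctx.graph, ctx.hierarchy, cfg
    )
    return net, history


def run_2d_study(seed: int = 1):
    """Full scaled-down 2D study: simulate, train, evaluate on test split."""
    ctx, tr, va, te = simulate_2d_dataset(seed, **STUDY_2D)
    net, history = train_gunet(tr, va, ctx, seed)
    table = evaluate_on_set(net, te, ctx)
    fs_net, _ = train_gunet(
        tr[: STUDY_FEWSHOT["n_train"]], va[: STUDY_FEWSHOT["n_val"]],
        ctx, seed + 1,
    )
    fs_table = evaluate_on_set(fs_net, te, ctx)
    return dict(
        ctx=ctx,
        splits=(tr, va, te),
        net=net,
        history=history,
        table=table,
        fewshot_net=fs_net,
        fewshot_table=fs_table,
    )


def run_transfer_3d(net, seed: int = 1, n_cases=4, sim_resolution=12,
                    inv_resolution=9):
    """Apply a trained network to LD images of 3D ball-phantom growths.

    Cases are drawn from the phantom distribution but kept only if the
    hemorrhage actually grows (nonzero change on the inverse mesh), so
    each case is a genuine growth-monitoring frame pair.  Returns the
    metric table comparing LD inputs and network outputs.
    """
    ctx = make_context(
        3, sim_resolution=sim_resolution, inv_resolution=inv_resolution
    )
    rng = np.random.default_rng(seed + 31)
    cases = []
    for _ in range(8 * n_cases):
        if len(cases) == n_cases:
            break
        (cand,) = make_training_set(1, ctx, rng)
        if cand.truth.max() > 0:
            cases.append(cand)
    table = evaluate_on_set(net, cases, ctx)
    return ctx, cases, table


def summarize(table) -> dict:
    """Mean metrics of an evaluation table (NaN-aware)."""
    return {
        "mean_mse_ld": float(np.nanmean(table["mse_ld"])),
        "mean_mse_net": float(np.nanmean(table["mse_net"])),
        "mean_abs_volume_error_ld": float(
            np.nanmean(np.abs(table["volume_error_ld"]))
        ),
        "mean_abs_volume_error_net": float(
            np.nanmean(np.abs(table["volume_error_net"]))
        ),
        "mean_cm_error_ld": float(np.nanmean(table["cm_error_ld"])),
        "mean_cm_error_net": float(np.nanmean(table["cm_error_net"])),
    }
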