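# eitgraph

Hemorrhagic-stroke monitoring with electrical impedance tomography
(EIT): a complete-electrode-model FEM forward solver, linear difference
(LD) imaging of conductivity changes, and a dimension-independent graph
U-net that post-processes the blurry LD reconstructions — trained on 2D
head slices, applied unchanged to 3D head volumes.

## Who this is for

Researchers in EIT / inverse problems who want a self-contained,
CPU-friendly reference implementation of the LD + learned-post-processing
monitoring pipeline, including phantom simulation, image-quality metrics
and a residual-network baseline.

## The model in brief

**Forward model (CEM).** For conductivity σ and current pattern I ∈ R^L,
the potential u solves ∇·(σ∇u) = 0 with electrode boundary conditions
u + z_ℓ σ ∂u/∂n = U_ℓ on e_ℓ, prescribed electrode currents, no flux
between electrodes, and ΣI_ℓ = ΣU_ℓ = 0.  Measurements are
V = U(σ) + e with white Gaussian e (std = 0.067% of the maximum
amplitude).

**LD imaging.** Given frames V1, V2 taken minutes apart,

    δσ̂ = argmin_δσ ‖L_δe(δV − J δσ)‖² + ‖R δσ‖²,   δV = V2 − V1,

with J the Jacobian of the voltage map at the best-fit constant
background σ0 and RᵀR the inverse of a squared-exponential spatial
correlation prior (correlation length = head width / 3).

**Graph U-net.** Nodal images over the mesh graph are processed with
graph convolutions H ↦ D̃^(−1/2)(A+I)D̃^(−1/2) H W, three per level,
channels 32→64→128→256 (~327k parameters), k-means cluster max-pooling
(×1/8 per level, 3 levels), clone-cluster unpooling, and concatenation
skips.  Weights are independent of the graph, so one trained network
runs on 2D and 3D meshes alike.  Training minimizes
Σᵢ ‖G_θ(δσ̂ᵢ) − δσᵢ‖² with Adam and early stopping.

## Worked example

```python
import numpy as np
from eitgraph.train import make_context, make_training_set
from eitgraph.study import train_gunet, summarize
from eitgraph.train import evaluate_on_set

ctx = make_context(2, sim_resolution=20, inv_resolution=12)
samples = make_training_set(30, ctx, np.random.default_rng(1))
net, _ = train_gunet(samples[:20], samples[20:24], ctx, seed=0,
                     max_epochs=120, patience_epochs=20)
print(summarize(evaluate_on_set(net, samples[24:], ctx)))
```

Output (a couple of minutes on one CPU):

```
{'mean_mse_ld': 0.0005770498917229481, 'mean_mse_net': 0.0004543540822456006,
 'mean_abs_volume_error_ld': 10.741417800968266,
 'mean_abs_volume_error_net': 3.3076485582088377,
 'mean_cm_error_ld': 3.5119723968734, 'mean_cm_error_net': 2.4393142975794855}
```

`mean_mse_*` compare reconstructions to the true conductivity change in
(S/m)²; `mean_abs_volume_error_*` compare half-maximum region areas
(cm² in 2D) and `mean_cm_error_*` centroid distances (cm).  The network
columns should beat the LD columns — the learned post-processing shrinks
the blurred LD support toward the true expansion.

A command-line interface mirrors the library:

```bash
eitgraph simulate --dimension 2 --n-pairs 24 --out data.h5
eitgraph train --dataset data.h5 --out net.h5
eitgraph evaluate --dataset data.h5 --network net.h5 --out metrics.csv
eitgraph fixtures disc-coarse
eitgraph demo
```

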