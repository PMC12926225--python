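# Methods

## Problem setting

Electrical impedance tomography (EIT) for bedside monitoring of
intracerebral hemorrhage: small currents are injected through scalp
electrodes and the induced electrode voltages are measured repeatedly.
Because blood is several times more conductive than brain tissue, growth
of a bleed between two measurement frames appears as a localized positive
conductivity change.  The package implements the full monitoring
pipeline on simulated head phantoms:

1. **Forward model** — complete electrode model (CEM) solved with
   piecewise-linear finite elements;
2. **Linear difference (LD) imaging** — one-step regularized
   reconstruction of the conductivity change between two frames;
3. **Graph U-net post-processing** — a learned, dimension-independent
   sharpening of the blurry LD images, trained on 2D samples and
   applicable unchanged to 3D mesh graphs.

## Forward model

The potential satisfies `div(sigma grad u) = 0` with CEM boundary
conditions: under electrode `l` with contact impedance `z_l`,
`u + z_l sigma du/dn = U_l`; the electrode current integral equals the
injected current; no current flows between electrodes; currents and
voltages sum to zero.  The FE discretization couples the nodal potential
with the L electrode voltages; the zero-mean voltage ground is enforced
by one Lagrange multiplier, giving a symmetric sparse system factorized
once per conductivity and reused across all current patterns and the
adjoint solves.

The voltage Jacobian with respect to the nodal conductivity coefficients
uses the standard adjoint identity
`dU_l^(j)/dsigma_h = -int phi_h grad(u_j).grad(w_l)`,
with `w_l` the solution for a unit load on electrode `l`'s voltage
equation.  A directional finite-difference check against the forward map
agrees to ~1e-4 relative error on the test meshes.

The linearization point `sigma0` is the spatially constant conductivity
minimizing `||V1 - U(sigma0 1)||^2`, found by a bounded scalar search on
`log sigma0` (bounds 1e-3–3 S/m, tolerance 1e-6).

Units: mesh coordinates in cm (converted internally to metres), currents
in mA, conductivities in S/m, contact impedances in Ohm m^2 (default
1e-3, uniform, identical for simulation and inversion — difference
imaging is insensitive to the static contact layer), voltages in volts.

## Phantoms

Layered head domains — skin and skull shells of 0.7 cm over a brain
region — with conductivities 0.06948 S/m (skin, brain), 0.009 S/m
(skull) and 0.312 S/m (hemorrhage); per-phantom tissue factors are drawn
uniformly from [0.75, 1.25] and shared by both frames of a pair.  The 2D
head is an 18 cm disc-like outline with 16 boundary electrodes of 2 cm
(the outline's ellipticity is configurable; the default is circular
because the bleed-radius range below requires a brain region of at least
7.47 cm radius).  The 3D head is a layered 18 cm ball with 32 electrodes
on four rings; pairwise injections pair electrode `j` with `j+16`.

The initial bleed is a disc/ball of radius uniform in [1.5, 7.47] cm;
the expansion is a half-ellipse/half-ellipsoid centred at the bleed
center, flat face through that center, main semi-axis uniform in
[1.5, 7.47] cm along a uniformly random direction, secondary semi-axes
equal to the initial radius.  Placement (not size) is redrawn when a
draw touches the skull, so accepted radii stay uniform.  A consequence
of the center attachment is that draws with main axis shorter than the
initial radius produce exactly zero growth; such zero-change pairs are
kept — they are legitimate monitoring frames (the "0.00 ml" situation)
and teach the network to suppress noise-only inputs.

Measurement noise is i.i.d. Gaussian with standard deviation 0.067% of
the maximum noiseless amplitude over the simulated dataset.

## LD imaging

`min_d ||L_de(dV - J d)||^2 + ||R d||^2` solved via its normal
equations with a dense Cholesky factorization.  The difference-noise
variance adds the two frame variances; a floor of `1e-6 max|dV|`
replaces missing noise metadata.  The prior covariance is a squared
exponential `s^2 exp(-|x_i-x_j|^2/(2 b^2))` with `b` chosen so the
correlation falls to 1% at one third of the head width, a 1e-6 diagonal
stabilizer, and `R` the inverse Cholesky factor; the variance scale
defaults to (0.1 S/m)^2.  Simulation and inversion use different meshes
(finer simulation mesh) so reconstructions are never tested against
their own discretization.

## Graph networks

Mesh graphs use simplex edges; convolutions aggregate with the fixed
symmetric normalizer `D^-1/2 (A+I) D^-1/2`, so all trainable tensors are
channel-shaped and independent of any graph.  Pooling hierarchies come
from geometric k-means on node coordinates (3 levels, each keeping
~1/8 of the nodes, fixed seed); pooling takes per-channel cluster
maxima, unpooling clones cluster features to members, and coarse graphs
connect clusters with adjacent members.

The U-net uses channels 32-64-128-256 (doubling reproduces the intended
~327k parameter count: 326,785), three convolutions per level, ReLU
after every convolution except the final 32-to-1 output convolution,
skip connections by channel concatenation, biases included, Glorot
initialization.  Inputs are divided by their maximum absolute value and
outputs rescaled by the same factor, which transfers amplitudes between
the 2D training images and 3D inference.

The residual baseline (gResNet) stacks 10 blocks of 3 convolutions with
identity skips at 32 channels inside a *global* residual
(`out = x + projection(blocks(lift(x)))`), so the all-zero network is
the exact identity — a natural parameterization for a post-processor
that learns a correction.

A deliberate property of the fixed aggregation is that it smooths at
every convolution; the network cannot reproduce sharp nodal edges
exactly, so even a single training sample has a representational loss
floor (roughly half the initial loss on our fixtures).  Training is
judged by the image metrics, not by driving the nodal MSE to zero.

Both networks are implemented directly in NumPy with hand-written
reverse-mode gradients (verified against finite differences) and Adam
(lr 1e-3 by default).  Training minimizes the mean squared nodal error
on the inverse mesh with early stopping on validation loss (patience 50)
and restores the best-validation weights.  The studies train with
mini-batches of 8 regardless of dataset size and require a minimum of
150 epochs before early stopping may trigger: with few optimizer steps
per epoch, the validation loss of a small validation set wiggles around
the all-zero-output level at initialization, and its noise minimum would
otherwise win the best-validation selection before any real learning.

## Metrics

Volume-weighted nodal MSE (lumped FE nodal measures); PSNR with the
truth's maximum as peak (undefined for a zero truth, mirroring "n/a"
cases); center-of-mass distance and signed volume error between
half-maximum regions, each image thresholded at half its own positive
maximum.  A truth with no positive part contributes zero detected
volume, so the volume error of a zero-change frame equals the
reconstruction's spurious artifact volume.  Analytic sphere/cylinder
volumes provide the closed-form bookkeeping for growth-case labels.

## Desk-scale study sizes

The full-scale experiments (thousands of samples, 10^4–10^5-node
meshes) are replaced by a single-CPU study whose *properties*, not
printed values, are checked:

* 2D: simulation mesh ~1.8k nodes, inverse mesh ~0.8k nodes, 100
  train / 20 validation / 20 test pairs, up to 300 epochs;
* few-sample regime: 20 train / 4 validation from the same pools;
* 3D transfer: ~8.2k-node simulation and ~3.6k-node inverse ball
  meshes (node spacing ~1 cm, so the thinnest expansion shells span at
  least one mesh edge), 4 random growth cases — draws with an actual
  nonzero change on the inverse mesh — processed by the 2D-trained
  network.

Expected outcomes: the trained network improves mean test MSE and mean
absolute half-max volume error over its LD inputs in 2D, the few-sample
network still beats LD on MSE, and the 2D-trained network reduces
|volume error| on at least 3 of 4 3D cases.

## What the synthetic data does not capture

Phantoms are concentric layered geometries with piecewise-constant
tissues; real heads have CSF, anisotropic skull, gyri, and
patient-specific shape.  Noise is white and Gaussian at a single
dataset-level amplitude; real electrode drift, contact changes and
motion are absent.  Electrode positions are exact and contact
impedances known.  Passing the study therefore demonstrates the
pipeline's internal consistency and the dimension-transfer property of
the graph formulation, not clinical performance.

## Known limitations

* Delaunay meshing of structured point sets gives adequate but not
  optimal element quality; electrode patches are unions of boundary
  facets, so effective electrode sizes vary at coarse resolution.
* The dense prior factorization and normal-equation solve limit inverse
  meshes to a few tens of thousands of nodes.
* k-means hierarchies depend on a seed; a trained network should be
  shipped with (or deterministically rebuild) its cluster hierarchies.
* Permittivity, multi-frequency measurements and nonlinear
  reconstruction are out of scope.
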