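# Methods

## Problem

Aortic regurgitation (AR) produces a thin, fast diastolic jet through the
incompletely closed aortic valve.  4D-flow MRI measures all three velocity
components over a volume but, at 1-3.5 mm resolution, cannot resolve the
vena contracta (< 3 mm wide for mild AR).  `jetsr` builds the full pipeline
for learning a x4 volumetric super-resolution operator for such jets from
synthetic paired data: high-resolution (HR) velocity fields of idealised
constricted-vessel flows, a forward model of low-resolution (LR)
phase-contrast MR acquisition, patch-based 3D convolutional networks, and
velocity-field evaluation metrics.

## Flow synthesis

### Geometry catalogue

Twenty Venturi-style geometries: a cylindrical vessel of inlet radius `R_I`
with a constricted waist of radius `R_C` representing the valve orifice.
Geometries 1-10 vary (`v_I`, `R_I`, `R_C`); geometries 11-20 inherit
geometry 3's radii and inlet velocity and add an angle `theta` (20-40
degrees), an in-plane offset `delta` (1.5-3 mm), or both, in a named
direction, producing eccentric jets.  The flow axis is +x; "upward" maps to
+y, "downward" to -y, "sideways" to +z; offset-only geometries with no
named direction use +y.

### Analytic surrogate

HR fields come from an analytic surrogate, not a Navier-Stokes solver.  The
network needs the statistical structure of regurgitant flow — a thin fast
jet, eccentricity, no-slip walls, a diastolic waveform — rather than
solver-accurate physics, so the field is assembled from closed forms:

- Upstream of the waist: parabolic pipe flow,
  `v(x, y) = v_I (1 - (x^2 + y^2)/R_I^2)` (flux `pi R_I^2 v_I / 2`).
- Through and past the waist: a Gaussian-radial-profile jet of width
  `sigma_0 = R_C / sqrt(2)` along the waist centreline.  The core speed
  follows flux conservation, `V_0 = jet_gain * v_I R_I^2 / (2 R_C^2)`,
  which for the catalogue lands in the 2-5 m/s range typical of AR jets
  (e.g. geometry 1: 3.75 m/s).  `jet_gain` (default 1) repositions peaks if
  needed.  Past the waist exit the centreline speed decays as
  `1/(1 + s/20 mm)` and the width grows as `sqrt(1 + s/20 mm)` — a crude
  entrainment model; the surrogate carries no downstream co-flow beyond the
  jet itself.
- The waist centreline ramps from the vessel axis to offset `delta` over a
  cosine entrance taper and then drifts at `tan(theta)` per mm, clamped so
  the channel stays inside the vessel; the jet follows the same (clamped)
  path, which keeps the jet core inside the fluid mask at high angles.
- The two regimes blend with a cosine weight over the 4 mm entrance taper.
- Time dependence is separable: every frame is the spatial field scaled by
  the envelope `g(t) = (t/tau) exp(1 - t/tau)` — zero at t = 0, unit peak at
  `tau`, slow decay — emulating rapid early-diastolic filling.  With 71
  frames at dt = 1 ms the window is 70 ms; `tau = 15 ms` puts the peak at
  ~frame 15.  The separable form also makes frame streaming cheap (one
  spatial field per geometry).
- No-slip is enforced by zeroing velocity outside the mask and in the
  one-voxel boundary layer (binary erosion).  In-plane divergence-freeness
  is *not* enforced: the surrogate provides plausible structure, and a
  solenoidal projection would add machinery the training task does not
  need.

The geometric fluid mask is analytic (point-in-channel).  A k-NN masking
path (`knn_mask`, majority vote over the `k` nearest labelled points via a
KD-tree, default k = 1) mirrors how masks are built from unstructured
solver meshes and is exercised against synthetic surface/interior point
clouds.

### Grids

Default HR grid: 0.25 mm isotropic over 64 x 24 x 24 mm (256 x 96 x 96
voxels), so the LR grid after x4 downsampling is 1 mm / 64 x 24 x 24
voxels.  The spacing is chosen by a hard constraint: a 12-voxel LR patch
spans 12 mm of cross-section at 1 mm LR voxels, and a 5 mm-radius vessel
fills up to `pi 25 / 144 = 0.55` of it, comfortably above the 20 % minimum
fluid fraction used in patch sampling.  At 0.5 mm HR spacing (2 mm LR) the
same patch spans 24 x 24 mm and the bound becomes unreachable (max ~0.14),
so coarser grids are only useful for whole-series checks, not patch
sampling.  Grid shape and spacing are fully configurable; tests additionally
use a 24 x 12 x 12 mm "patch grid" with a compressed geometry (upstream
length 6 mm, waist 4 mm) for speed.

## MR acquisition model

Per velocity component `j` with encoding velocity `venc_j`:

1. Complex image `I exp(i pi v_j / venc_j)` on the HR grid, with magnitude
   `I` (the draw's intensity) in fluid, `I/3` in static tissue, and
   optionally ~0 in air.  The fluid/tissue contrast is what lets the
   magnitude channels carry mask information into the network.
2. Downsampling by central k-space truncation (crop to 1/4 of each axis,
   inverse FFT, amplitude-preserving for DC) — the standard frequency-domain
   model of resolution loss in MR.
3. Zero-mean Gaussian noise of std `sigma = I / 10^(SNR_dB/20)` added
   independently to the real and imaginary parts *of the LR image* (noise
   after truncation).
4. Velocity decoded from the noisy phase, `v = venc * angle / pi`; decoded
   values are inherently wrap-limited to [-venc, venc].  Phase wrapping is
   exact through the complex exponential: a 1.5 venc velocity decodes to
   -0.5 venc.

Augmentation policy, drawn per frame and per component: VENC from the menu
{0.3, 0.6, ..., 6.0} m/s — the smallest value strictly above the
component's peak speed with probability 0.9, or (with probability 0.1) a
deliberately aliasing value 0.3-0.6 m/s *below* the peak, snapped to the
nearest menu value and floored at 0.3; intensity uniform over the integers
60-240; SNR uniform over [14, 17] dB.  Aliasing flags are recomputed from
the actual field maxima, not the branch taken.

## Patches and stitching

From each frame, 10 LR corners are rejection-sampled (budget 1000 draws)
until at least 20 % of the 12-voxel LR cube is fluid; patches may overlap
(random placement doubles as translation augmentation).  Each accepted
patch is duplicated under one of the 23 non-identity proper cube rotations:
spatial axes permute/flip, the velocity *vectors* transform by the same
matrix, magnitude channels and the VENC triple permute with their
components, and the duplicate copies the base patch's noise.  20 patches
per frame x 71 frames = 1420 pairs per geometry.

Full-volume prediction splits the LR volume on a stride-8 lattice
(stride = patch size - 4, clamped at the far edge), and stitches 48-voxel
SR patches with 4 HR voxels stripped from each patch side except where a
patch touches the volume boundary; residual overlaps resolve
last-writer-wins in lexicographic lattice order.  Feeding ground-truth HR
patches through this path reproduces the HR volume exactly.

## Networks

All variants share the frame: velocity and magnitude input branches (two
3^3 convs each), a 1x1x1 merge, `lr_blocks` = 8 blocks in LR space, a
central non-learned trilinear x4 resize + conv, `hr_blocks` = 4 blocks in
HR space, and three single-component output heads (one 3^3 conv + linear
3^3 conv to 1 channel).  Blocks:

- res: two 3^3 convs with identity skip (activation after the add);
- dense: four 3^3 layers of growth 16 with cumulative concatenation and a
  1x1 transition back to 64 channels;
- csp: a quarter of the channels runs through a 4-layer partial dense
  block and 1x1 transition, re-merged with the bypass through a second 1x1
  transition.

Activations are LeakyReLU(0.2); the default initialisation is
fan-in-scaled Gaussian from a documented seed.  A second option,
`init="dirac"`, places a centre-tap identity over the leading channels on
top of down-scaled noise and zeroes each residual block's second
convolution, so the trunk passes its input through at initialisation.
This matters at small widths and short schedules: a probe that
linearly decodes the input from each stage's features shows per-voxel
R^2 decaying ~0.7x per randomly-initialised conv stage, and a 4-channel
He-initialised net converges to the zero-output solution within the
step budgets used here.  Identity-preserving initialisation removes that
barrier without changing the architecture or parameter count.  At the 64-channel defaults the parameter counts
are res 3,343,619 (3.34 M), dense 2,612,483 (2.61 M), csp 1,667,075
(1.67 M) — the res > dense > csp ordering that motivates the CSP design.
The internal conv layout of the dense/csp blocks is under-determined by
their published descriptions, so their totals are what the canonical
definitions above give; growth rate, dense depth and the CSP split
fraction are spec fields for retuning.

The framework is numpy + numba: channels-first 3D convolutions as
row-vectorised numba kernels (with a pure-numpy shift-and-GEMM twin used as
an oracle in tests), exact adjoint backward passes, separable trilinear
resize via per-axis interpolation matrices, and Adam.  Weight gradients
accumulate in float64 regardless of activation dtype.

## Training

Loss: mean squared velocity error summed over components, computed as
*separate means* over fluid and non-fluid voxels and added — the two
regions are heavily imbalanced within a patch and separate means equalise
their influence.  The velocity-gradient smoothing term used by earlier
flow-SR work is deliberately omitted.  The loss operates on
VENC-normalised velocities (inputs and targets are scaled to [-1, 1] per
component), so reported losses are dimensionless; validation uses the
physical-scale relative speed error (RE), computed per patch and averaged.
Optimiser: Adam, initial learning rate 1e-4 divided by sqrt(2) every 14
epochs, batch 16, 200 epochs at full scale.  Checkpoints are kept every
epoch (best-by-validation-RE and last); `train` restores the best weights
before returning.

### Scaled-down demonstration

Full-scale training is a GPU-week workload; the repository's convergence
demonstration (and its test) runs the res variant at channels = 4,
2 LR + 1 HR blocks, single-conv heads and dirac initialisation, on 200
patches from one geometry for 20 epochs, validated against patches from
a different geometry and three held-out frames.  The short schedule uses
an initial learning rate of 1e-2 with the sqrt(2) decay applied every 5
epochs (the 1e-4 / 14-epoch schedule is calibrated to 200 epochs).
Training and evaluation frames sit near the envelope peak: at early
frames the arctangent RE is dominated by near-zero-speed voxels, where
it measures output-suppression rather than reconstruction.  These sizes
are the package's own choice of demonstration scale; the success
criteria are that validation RE falls below its untrained value and that
the stitched prediction beats trilinear upsampling of the noisy LR
volume on mean RE over the held-out frames.

Two properties of the data make this a genuine learning task even at
tiny scale.  First, static tissue carries a third of the fluid's
magnitude, so its decoded phase noise is three times stronger: plain
pass-through of the LR velocities is punished by the non-fluid loss
term, and the optimal small-capacity behaviour couples attenuation with
a magnitude-driven fluid gate.  Second, the jet itself is largely
destroyed by the x4 k-space truncation, so jet recovery relies on the
learned prior rather than the input.

## Evaluation

- RE: `mean over fluid voxels of arctan(||v' - v|| / (||v|| + 1e-4))`,
  radians, bounded by pi/2; the arctangent caps the
  penalty where true speed is near zero.  Fluid-only by construction.
- RMSE and SSIM per Cartesian component.  SSIM uses the canonical
  Wang-2004 settings (3D Gaussian window sigma 1.5, width 11, population
  statistics, K1 = 0.01, K2 = 0.03) on raw velocity values with the data
  range taken from the HR component; constant-and-identical volumes score
  1 by convention.
- Agreement: OLS of SR on HR voxel values (slope/offset) and Bland-Altman
  bias with 1.96 sd limits, pooled over components, optionally restricted
  to an axial slab covering the constricted section.

## Numerical choices and edge cases

- Phase wrap convention: (-pi, pi], boundary to +pi; ties are measure-zero.
- Trilinear resize is corner-anchored (output sample i sits at i/factor in
  input index space): DFT/k-space downsampling places LR sample j exactly
  on HR sample 4j, so this convention makes upsampling the exact spatial
  inverse of the truncation grid, preserves constants, and reproduces LR
  samples at the shared lattice points.
- k-space crop uses the fftshift-centred block; axes not divisible by the
  factor are zero-padded up front.
- LR fluid mask: a block is fluid iff >= half its HR voxels are.
- Empty loss regions contribute 0; empty fluid masks raise.
- Patch rejection sampling raises after 1000 failed corner draws.
- All randomness flows from explicit seeds (`numpy.random.Generator`);
  flow synthesis itself is deterministic and bit-reproducible.

## What the synthetic data does not show

The surrogate has no turbulence, no pressure coupling, no temporal
dynamics beyond a separable envelope, no wall motion, and its downstream
decay law is ad hoc.  The MR model omits k-space trajectory effects,
eddy-current and Maxwell phase errors, partial-volume tissue signal and
temporal undersampling.  Passing tests therefore demonstrate that the
pipeline's bookkeeping, encodings, losses and optimisation behave as
specified and that the networks can learn denoising/sharpening operators
on jet-like fields — not that a network trained here transfers to in-vivo
4D-flow MRI.

## Known limitations

- Dense/CSP parameter totals differ from the res-anchored reference counts
  (2.61 M vs 2.55 M, 1.67 M vs 2.08 M); see the block note above.
- Full-size (0.1 mm-class) grids and 200-epoch training are supported by
  the code paths but not exercised in CPU-budget tests.
- The numba kernels are single-threaded by design (deterministic, and the
  target environment is one CPU).
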