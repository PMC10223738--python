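# Methods

## The model

The package simulates an all-optical diffractive deep neural network
(D2NN): a stack of `L` passive diffractive layers separated by free-space
gaps of length Δz, illuminated by a coherent monochromatic source (He-Ne,
λ = 632.8 nm by default). A grayscale image in [0, 1] amplitude-modulates
the input plane (zero phase). Between planes the scalar field propagates by
the angular spectrum method (ASM),

    u_out = F⁻¹[ F[u_in] · H(u,v) ],    H = exp(j·2π·γ·Δz),
    γ = sqrt(1/λ² − u² − v²),

with evanescent components (negative radicand) hard-zeroed. Each layer
multiplies the field pixel-wise by a passive modulation t = a·exp(jφ),
|t| ≤ 1. After the last gap, two rectangular detector regions on the output
plane integrate the arriving light; the readout per class is A_i = Σ|u|
("magnitude" mode, the default) or Σ|u|² ("intensity" mode). The predicted
class is argmax A_i, ties to the lowest index.

Assumptions: scalar diffraction (no polarization), full coherence, lossless
propagation medium, thin layers (pure multiplicative modulation), uniform
sampling. These are the standard D2NN simulation assumptions.

## Propagation numerics

* **Conventions.** Forward transform kernel exp(−j2π(ux+vy)) (numpy
  default); time convention exp(+jkr) for outgoing waves; arrays indexed
  (row, col) = (y, x); physical origin at the array centre; frequency
  samples at multiples of 1/(pad·n·pitch).
* **Padding.** `pad_factor=2` (zero-pad, crop after the inverse transform)
  is the network default: it suppresses circular wraparound and models the
  finite aperture of the layer stack. `pad_factor=1` gives the cyclic
  transform, which is *exactly* unitary on the propagating band and an
  exact semigroup (two Δz steps equal one 2Δz step); the physics tests use
  it for the energy-conservation, invertibility and composition checks.
  With padding + cropping, light that diffracts past the aperture is
  deliberately discarded, so power decreases and composition is only
  approximate — that is the physical behaviour of a finite stack, not an
  error.
* **Oracle route.** `propagate_rs_direct` evaluates the exact discrete
  Rayleigh–Sommerfeld superposition O(n⁴)-style with the impulse response
  w = (1/2π)(Δz/r)(1/r − jk)e^{jkr}/r. Cross-checks between the two routes
  use a pitch matched to the distance, pitch = sqrt(λ·Δz/(4(n−1))) — the
  largest spacing that samples the kernel alias-free over the full offset
  window — pad_factor 4, and random fields band-limited to half Nyquist
  with a Gaussian envelope. In that regime the routes agree to ~1e−4
  relative L2. At the network's own geometry (n = 200, 4 µm pitch, 10 mm
  gaps) the walk-off of the highest represented frequency (~0.79 mm) fits
  the padded half-aperture (0.8 mm), so the ASM is self-consistent there
  too. Comparing the routes on *white* fields at shrunken grids is not
  meaningful: near-Nyquist plane-wave components leave the tiny sampled
  window over millimetres of propagation, so the exact sum suppresses them
  while the cyclic transform wraps them.

## Architecture and training

Published geometry, used as the defaults: 5 layers, 200×200 neurons
(detection) or 400×400 (classification), 4 µm pitch (0.8/1.6 mm layers),
Δz = 10 mm everywhere including input plane → layer 1 and last layer →
detector plane; 50×50 inputs upsampled by nearest-neighbour replication.
Detector layout (the source publication never specifies it): two squares,
each 20 % of the grid side, vertically centred, horizontally centred at
25 % / 75 % of the width; class 0 (no-nodule / benign) left, class 1
(nodule / malignant) right.

Two task-specific readout normalizations:

* **Detection** — A'_i = A_i / (A_0 + A_1 + b_0 + b_1); the nonnegative
  biases guard near-dark windows. b_0, b_1 are trained (softplus
  parameterization, initialized at 0.01). Loss: softmax cross-entropy on A'.
* **Classification** — A'_i = α·A_i / max(A_0, A_1), α = 1 by default (only
  the ratio to the one-hot target matters). Loss: squared error against the
  α-scaled one-hot.

Phases are unconstrained reals (wrapped mod 2π only at export); amplitudes
are frozen at 1 in the default phase-only mode and clipped to [0, 1] when
trainable. Initialization: phases i.i.d. uniform [0, 2π) from a seeded
generator.

Gradients are computed by a reverse-mode adjoint pass written for this
exact chain: the cotangent seeded at the detector plane (∂loss/∂A mapped
through u/|u| for magnitude readout, 2u for intensity) is pulled back
through each gap with the conjugate transfer function and through each
layer with conj(t), accumulating dL/dφ = −Im(u·conj(g)) per pixel.
Finite-difference checks (central, step 1e−4 rad) agree to ~1e−8 relative.
The optimizer is Adam (β = 0.9/0.999) with the published learning rates
(0.005 detection / 0.001 classification), batch 64, 120 epochs at full
scale. Training is bit-reproducible for a fixed seed on one thread.

Dataset handling follows the published protocol: case-level splits in the
ratio 8:17:75 (validation:test:training) by seeded shuffle +
largest-remainder rounding, optional k-fold cross-validation, optional
class rebalancing (seeded subsampling of the over-represented class) and
8-fold dihedral augmentation (4 rotations × optional flip).

## Synthetic data

Real thoracic-CT patch data with radiologist annotations is not bundled;
`d2nn.synthetic` generates a controllable stand-in:

* **Detection patches** (50×50): background = per-patch grey level
  (0.20 ± 0.10 uniform, emulating heterogeneous parenchyma brightness) plus
  band-limited texture (Gaussian-filtered white noise, correlation 4 px,
  amplitude 0.08). The nodule class adds a radially symmetric smoothstep
  blob, radius uniform 5–9 px, contrast 0.5, edge softness 2.5 px.
  `center_jitter` (default 0) offsets the blob uniformly, used for
  scan-robust training (below).
* **Benign/malignant pairs**: same background family; benign = the smooth
  blob; malignant = radius ×1.6, boundary modulated by low-order random
  harmonics (irregularity 0.25) plus 6 Gaussian angular spicules.
* **Slices**: the patch texture plus large-scale dark lung-field shading
  (correlation 25 px, amplitude 0.06) and a few bright vessel/rib-like
  vertical ridges; nodules planted at rejection-sampled centres ≥ 25 px
  from borders and ≥ 50 px apart, centres returned as ground truth.

What this does **not** emulate: Hounsfield-unit statistics, anatomical
structure (airways, pleura), 3-D partial-volume effects, scanner noise, or
the hard ambiguous cases of real nodules. Passing tests therefore
demonstrate that the optical model, gradients and pipeline work end to end
— not clinical-level performance on real CT.

## Reduced-scale study conditions

Full-scale training (200²–400² neurons, 120 epochs, thousands of patches)
is deliberately scaled down for the test suite and the acceptance script:

* **Learning check**: 100×100 grid, 3 layers, 200 training / 100 validation
  patches, 10 epochs, batch 64, lr 0.005. Reaches ≥ 0.95 held-out accuracy
  (measured 0.99 at seed 0).
* **Scan check**: same architecture trained 30 epochs on patches with
  centre jitter = stride/2 = 5 px — scan windows on the stride-10 lattice
  see nodules up to ~7 px off centre, and a diffractive network is not
  shift-invariant, so jittered training is what makes window-level
  classification transfer to scanning. One 300×300 slice with 5 planted
  nodules, window 50, stride 10, threshold 0.5, match radius 25 px.
  Raising the threshold prunes candidates and lowers recall, mirroring the
  published threshold behaviour.

## Numerical choices and edge cases

* Argmax ties (prediction, and the max in the classification
  normalization) resolve to the lowest class index, deterministically.
* Metrics with zero denominators (recall/precision/specificity/F1/MCC) are
  reported as NaN with an `undefined` flag, never silently 0.
* ROC: threshold sweep over distinct scores, trapezoidal AUC; tied scores
  move together, contributing half.
* Dark windows: magnitude readout uses u/|u| with the |u| = 0 limit set to
  0 in the adjoint; the detection biases keep normalization finite.
* Dataset PNGs are 16-bit grayscale (quantization ≤ 0.5/65535); network
  checkpoints are `.npz` archives with a JSON config block, save → load →
  save is bit-exact.
* NaN loss aborts training with a diagnostic rather than continuing.

## Known limitations

* No optical nonlinearity between layers — the whole network is linear in
  the field, which caps attainable decision boundaries (energy routing).
* At 400×400 the diffraction angle does not give full plane-to-plane
  connectivity; acknowledged, no compensation applied.
* The "sum amplitude" (Σ|u|) vs "intensity" (Σ|u|²) readout ambiguity in
  the source description is resolved by implementing both; magnitude-sum is
  the default and the mode is recorded in every run manifest.
* Brute-force RS propagation is O(n⁴) and intended only for n ≤ 64 oracle
  use.
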