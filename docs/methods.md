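# Methods

`usncal` implements a semi-automatic freehand ultrasound probe calibration
pipeline: a convolutional network localises the centroid of an
out-of-plane needle reflection in a B-mode frame, and a Procrustean
point-to-line registration with anisotropic pixel scaling solves the
image-to-tracker transform from a dozen or so (centroid, tracked needle
axis) observations. A synthetic water-bath phantom generates annotated
data so every stage is testable without an ultrasound scanner or a
magnetic tracker.

## The calibration model

A probe calibration is a homogeneous map `T` from image pixel
coordinates `(u, v, 0, 1)` to the coordinate frame of a tracking sensor
fixed to the transducer. Its 3×3 block factors as `R · diag(s_x, s_y,
s_z)`: a rotation times positive per-axis scales, where `s_x` and `s_y`
are the lateral and axial mm-per-pixel spacings. Each observation pairs
a pixel centroid `p_i` with a tracked needle axis `L_i` (tip + unit
direction); the estimate minimises the RMS point-to-line distance
(target registration error, TRE)

```
TRE(T)^2 = (1/n) Σ_i d(T·p_i, L_i)^2 .
```

**Solver.** An ICP-style outer loop alternates correspondence and
alignment: map the pixel points with the current `T`, project each onto
its line (the closest point), then solve the resulting point-to-point
anisotropic Procrustes problem and repeat until the TRE change falls
below 1e-9 mm (cap 500 iterations). The inner problem
`min Σ ‖R S p̃_i − q̃_i‖²` over demeaned sets is itself solved by exact
alternating steps: the rotation from the det-corrected SVD of the
cross-covariance of the scaled sources (the sign flip, when needed, is
applied to the column of the smallest singular value), each scale in
closed form `s_k = Σ p̃_ik (Rᵀq̃_i)_k / Σ p̃_ik²`, and the translation
from the centroids. Both loops are monotone, which the test-suite
asserts per step. The inner alternation starts from the isotropic
global-ratio scale so the first rotation solve is well conditioned, and
stops at a relative objective change of 1e-12 (cap 200).

**Identifiability.** All pixel points have zero elevation, so `s_z`
cannot be estimated; it is fixed to the mean of the in-plane scales. It
affects neither the TRE nor the extracted spacings. The model has 8
identifiable degrees of freedom (3 rotation, 3 translation, 2 scales)
and each pair contributes 2 constraints; the solver requires ≥ 6 pairs
for slack against near-degenerate geometry, and rejects pair sets whose
needle directions are all within 1° of parallel.

**Initialisation.** The ICP objective is non-convex. The fit multi-starts
from 8 poses: quarter turns about the image-plane normal, each with and
without a normal flip, with scales at a nominal isotropic 0.1 mm/px and
the translation chosen so the scaled pixel centroid lands on the centroid
of the per-line points closest to the mean needle tip (a tip+direction
line has no natural midpoint, so the mutual-closest-point centroid serves
as the lines' centre of mass). The lowest-TRE restart wins. In testing,
noiseless observations are recovered to < 0.01° rotation, < 0.01 mm
translation, < 0.1 % per-axis scale and < 1e-6 mm TRE across seeds.

**Spacing extraction.** For a `rotation × diag` block the singular values
equal the column norms, so the lateral/axial spacings are read off the
first two column norms; the implementation cross-checks the two and
raises if they disagree (shear present).

## The localisation network

The localiser maps a 128×128 frame (bilinear resize of the raw 8-bit
image, divided by 255) to the two centroid coordinates in the unit range:
each raw axis maps affinely from `[0, extent−1]` onto `[−1, 1]`; at the
native 356×589 geometry these are the integer ranges `[0, 355]` and
`[0, 588]`. Predictions invert that affine map against the *raw* frame
geometry and round half-away-from-zero (a symmetric, platform-stable
convention) to integer pixels; a prediction outside the frame raises a
retriable rejection — the caller captures a new frame. Because the unit
range is tied to each frame's own extent, frames recorded at other
imaging depths (4–8 cm, hence other heights) flow through the same code
path.

Architecture: five alternating valid (no-padding, stride-1) convolution
and 2×2/stride-2 max-pooling stages with filter counts
16/32/64/128/256 (first kernel 3×3, the rest 2×2), flatten to
3·3·256 = 2304 features, then fully connected layers of widths 1024,
128, 16 and 2; Leaky-ReLU (slope 0.01) on all pre-output layers, linear
2-unit output, Glorot-uniform initialisation. The default model carries
exactly 2 668 338 trainable parameters (174 720 of them convolutional),
an identity the tests pin; `build_model` refuses any conv/pool geometry
whose flatten length drifts from 2304. Stride-2 pooling is the only
pooling geometry compatible with that parameter count at this input
size.

The network is implemented directly on numpy arrays: im2col convolutions
(kernel weights stored in `(c_in, kh, kw)` order so the sliding-window
view reshapes into the column matrix without a transposed copy),
reshape-based pooling whose backward pass splits the gradient equally
among tied maxima (a deterministic subgradient), and dense layers. The
first convolution skips its input-gradient computation. Training is
mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the optimiser's
canonical defaults) on the mean-absolute-error loss in unit coordinates,
with an L2 penalty (coefficient 1e-5, entering through the gradient) on
convolutional kernel weights only, and per-epoch shuffling. Runs are
bit-reproducible under a fixed seed on a given BLAS.

**Full-scale protocol** (the reference configuration): batch 128, 150
epochs, learning rate 1e-4 for epochs 1–100 and 7e-5 afterwards.

**Desk-scale protocol** (`usncal.protocols.run_scaled_training`): 600
training / 150 validation / 100 test frames, batch 64, 40 epochs at
1e-3 stepping down to 3e-4 after epoch 25. With roughly a tenth of the
optimisation steps of the full protocol, the step size is scaled up an
order of magnitude and decayed once the loss flattens — the same
stepped-schedule shape at a size that trains in minutes on one CPU.
Success is judged by two measures: the validation MAE must fall well
below its first-epoch value, and the mean test-set pixel error must be
smaller than the mean rendered blob radius (a localiser is only useful
if it lands inside the reflection it points at).

## The synthetic phantom

The generator emulates the water-bath acquisition geometry, not
ultrasound physics:

* a ground-truth calibration with a uniformly random rotation, scales
  `(0.097, 0.102, mean)` mm/px and a translation within 500 mm of the
  tracker origin. The default spacings are consistent with a 6 cm depth
  spanning the 589-pixel axial extent (60 mm / 589 px ≈ 0.102 mm/px);
* needle lines constructed to pierce the image plane at a chosen pixel,
  with insertion angle uniform in 20–70° from the plane, uniform
  in-plane azimuth, and the tip 10–60 mm from the plane on a random
  side;
* tracker noise at the manufacturer-reported level: isotropic Gaussian
  tip displacement with RMS *norm* 1.2 mm (per-component σ = 1.2/√3)
  and a rotation of the direction about a uniformly random axis by a
  zero-mean Gaussian angle of RMS 0.5°;
* frames rendered as dim gamma-distributed speckle (mean intensity 6 of
  255) plus a Gaussian-profile elliptical reflection whose semi-minor
  axis grows linearly towards the far field (base 6 px, doubling over
  the full depth) and whose semi-major axis is the minor elongated by
  `1/sin(insertion angle)` along the needle's in-plane heading, followed
  by a weak decaying reverberation tail below the blob. Peak intensity
  230; tail amplitudes sit below the 60-intensity moment threshold so
  the intensity-weighted centroid of the above-threshold region stays
  within ~1.5 px of the requested centroid for interior placements.

Labels are always computed geometrically — intersect the noiseless
tracked line with the image plane via the inverse calibration, exactly
the construction used to annotate real acquisitions — never read back
from rendered pixels, so re-rendering with different speckle never moves
a label. Centroid targets are stratified over a 4×4 grid (corners
represented); out-of-bounds draws are resampled so requested counts are
exact. Frame `i` draws from a deterministic substream of the dataset
seed, making frames order-independent.

**What the phantom does not model**, and hence what passing tests do not
show about real data: wave-propagation speckle correlation, tissue
backgrounds, curvilinear fan geometry, reflection intensity profiles of
a real needle (the ellipse+tail is a phenomenological stand-in), probe-
or machine-specific artefacts, and temporal stream misalignment. The
published real-probe error figures (RMSE 0.62/0.74 mm) depend on
proprietary acquisitions and human annotators and are not reproduced
here; the synthetic studies demonstrate the *mechanics* — learnability
of the localisation task, exact noiseless recovery, the TRE plateau near
a dozen pairs, and end-to-end spacing recovery within 10 % under
realistic tracking noise.

## Numerical choices and degenerate inputs

* Parallel-line tolerance: a needle whose image-frame unit direction has
  |elevation component| < 1e-8 is rejected as in-plane.
* Half-away-from-zero rounding for pixel coordinates (symmetric and
  deterministic across platforms).
* Procrustes degeneracies: < 4 correspondences, collinear/coincident
  sources, or zero source variance on an identifiable axis raise
  explicit errors, as does a fitted non-positive scale.
* The capture loop aborts when more than half of the captured frames
  are rejected, signalling an unusable localiser; with a working model
  rejections are rare (the training data never contains out-of-bounds
  centroids, mirroring the culled acquisitions).
* Sample (n−1) standard deviation for the inter-rater statistic;
  population standard deviation for the spread of per-frame absolute
  errors. Both conventions are documented because neither is forced by
  the statistic's definition.

## Known limitations

* The network trains on synthetic reflections only; transfer to any
  real probe requires retraining on annotated acquisitions from that
  probe.
* The alternating Procrustes scheme is validated by parameter recovery
  and against a generic nonlinear least-squares oracle, not against any
  particular published update equations.
* No outlier rejection: a grossly wrong centroid (or needle pose)
  degrades the fit in proportion to its leverage.
* Single-threaded CPU training of the 2.7 M-parameter network is
  minutes per study at desk scale; the package does not target GPU
  throughput.
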