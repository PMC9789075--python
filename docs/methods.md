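# Methods

This note records the models, parameters and numerical choices behind
`accelt2`, in the order data flows through the toolkit.

## Signal model and synthetic phantoms

A T2-prepared snapshot gradient-echo acquisition is modelled as a set of
coil-combined magnitude images at echo times TE (knee/spine:
0, 12.9, 25.7, 51.4 ms; hip: 0, 10.4, 20.8, 41.7 ms), with per-pixel
mono-exponential decay `S(TE) = PD · exp(−TE/T2)`.  Magnitude noise is
Rician: two independent Gaussian channels of standard deviation
`noise_sigma × max(PD)` (default `noise_sigma` = 0.02), the real channel
carrying the signal.  This matches the statistics of coil-combined
magnitude images; in the background the magnitude mean is
`σ·√(π/2)`, which the test suite verifies empirically.

Phantoms place a thin curved band ("cartilage", 2–6 px thick, knee/hip)
or stacked ellipses ("IVDs", spine) inside an elliptical body on a
`(n_y, n_x, n_z)` grid (default 64×64×8; at least 8 slices so k_z
undersampling is meaningful).  Class T2 values are drawn per phantom from
the configured ranges — knee: background 20 ms, ROI 30–60 ms; hip:
background 20 ms, ROI 25–50 ms; spine: background 40 ms, ROI 60–130 ms —
chosen so the tissue of interest spans the upper part of each anatomy's
sigmoid-loss transition window.  Optional focal lesions (default 3) raise
T2 by +15 ms in small balls inside the ROI, giving the maps local
structure that the texture metrics and the ROI loss can act on.  The ROI
drifts by ≤ 2 px across slices and proton density is modulated smoothly
along z so the k_z spectrum is non-trivial.

What the phantoms deliberately do **not** model: anatomically realistic
geometry, B0/B1 artifacts, registration error (volumes are generated
aligned; the fitting stage therefore omits the rigid-registration step a
real pipeline needs), multi-coil sensitivity structure, and T1ρ
weighting.  Passing tests on phantoms therefore demonstrates correctness
of the algorithmic chain, not clinical performance.

## Retrospective undersampling

Undersampling acts on the two phase-encode dimensions (k_y, k_z) with the
readout fully sampled; DC sits at the grid centre (fftshift convention,
0-based indices).  Coverage is restricted to a centred ellipse occupying
0.70 of the rectangular grid (discretely calibrated to ±0.01; corner
k-space is never acquired).  Acceleration R is defined with respect to
ellipse-interior points, and the fully sampled central square — 5 % of
grid *area*, side `√0.05` of each extent rounded to odd so it is
symmetric about DC — counts toward the sampled points.

Masks are variable-density Poisson-disc patterns produced by dart
throwing in a seeded random candidate order, with exclusion radius
`r(d) = r₀ (1 + α d)` where `d` is the normalised elliptical radius and
`α = 2.0`.  The density law and α are not pinned down by the reference
protocol; a linear law with a single calibrated knob `r₀` reaches every
R in 2…12 and is center-weighted by construction (the sampled fraction
decreases over elliptical-radius tertiles, asserted by a property test).
Calibration first fixes the target point count `m* = round(n_ellipse/R)`
(if no integer count lies within the 2 % tolerance the call fails
loudly), bisects `r₀` to the sparsest pattern with ≥ m\* points, then
deterministically removes the latest-accepted darts down to exactly m\* —
removal cannot violate the exclusion radii, and the whole construction is
bit-reproducible from `(seed, R, echo_index, grid)`.  Each echo gets a
unique pattern via a seed offset.

Unsampled (k_y, k_z) lines are initialised from the sampled echo with the
closest TE (ties resolved toward the earlier, higher-SNR echo); lines
sampled at no echo are zero-filled.  Aliased magnitude images are the
inverse FFT of the shared k-space.

## Mono-exponential fitting

`fit_t2` estimates (A, T2) per pixel by Levenberg–Marquardt on
`A·exp(−TE·rate)` with `rate = 1/T2`, initialised from the least-squares
line through (TE, log S).  The damped 2×2 normal equations are solved in
closed form for all pixels simultaneously, with per-pixel damping
factors, so the fit of a full volume takes well under a second.  Defaults:
T2 bounds [1, 300] ms (non-decaying pixels clamp to the upper bound and
are flagged rather than diverging — bounded maps are required by the
losses and by GLCM quantisation), signal floor 1e-3 (TE=0 signal at or
below it marks the pixel invalid, sentinel 0), 30 iterations, relative
convergence tolerance 1e-10.  Magnitude (Rician) bias is *not* corrected
— plain least squares on magnitudes, matching standard practice; at 1 %
noise the induced median bias is below 2 % (verified by Monte Carlo).
The fit is invariant to uniform positive scaling of the signal.

## Loss functions

The training objective is
`L = λ_L1 L_L1 + λ_L1,φ L_L1,φ + λ_SSIM L_SSIM + λ_Feature L_Feature`.

* The sigmoid operator `S(x) = y_l + (y_h−y_l)(1+exp(−(10/(x_h−x_l))(x−(x_l+x_h)/2)))⁻¹`
  up-weights errors at high T2.  Presets: knee (0, 100 ms, 0.1, 1.0), hip
  (0, 60 ms, 0.5, 1.0), spine (0, 150 ms, 0.25, 1.0).
* `L_L1` and `L_L1,φ` are **mean** absolute differences of sigmoid-scaled
  maps (globally / over ROI pixels).  The reduction is a package choice:
  a mean keeps the λ search ranges comparable across image sizes.
* `L_SSIM = 1 − SSIM` on maps clipped to [0, 1.5·x_h] and rescaled to
  [0, 1]; uniform 7×7 window, sample covariance, stabilisation constants
  K1 = 0.01, K2 = 0.03 — the common library default, which the test suite
  cross-checks against scikit-image exactly.  SSIM needs a declared
  dynamic range; 1.5·x_h covers the tissue range with headroom.
* `L_Feature` compares deep convolutional features of the two maps:
  inputs are bilinearly resized to 224×224 (implemented as two fixed
  interpolation matrices, hence differentiable), scaled to [0, 1] by the
  same 1.5·x_h range, tripled along channels and normalised with the
  standard per-channel means 0.485/0.456/0.406 and s.d.
  0.229/0.224/0.225.  The extractor is dependency-injected: a pretrained
  19-layer VGG-style network's mid-depth (21st-layer) output where
  weights are available, else `RandomConvFeatures` — a fixed-seed random
  strided conv stack with the same interface.  Random convolutional
  features preserve local-structure differences well enough for a
  perceptual penalty and keep every result reproducible offline.

λ search ranges (constrained random search, 15 iterations × 10 epochs):
knee λ_L1 = 1, λ_L1,φ ∈ [50, 150], λ_SSIM ∈ [0, 2], λ_Feature ∈ [0, 0.5];
hip 1, [0, 3], [0, 2], [0, 1]; spine 1, [1, 10], [10, 100], [5, 55].  The
search scores validation ROI NRMSE (ascending) and ROI Pearson r
(descending) and picks the minimum rank sum — the combiner is a package
choice, since the two criteria are stated without one.

All components are differentiable through `accelt2.nn`, a compact numpy
reverse-mode autodiff engine written for this package (tensors, conv /
transposed-conv / batch-norm primitives, Adam).  Gradients of every
primitive are verified against central finite differences.

## Architecture

Three variants map 4 aliased echo images to a T2 map.  The **full** model
runs every echo through the *same* 5-layer stream of 3×3 stride-1
convolutions (depths 64, 128, 256, 512, 1; weight sharing across echoes
is what makes the front end recurrent), with a residual connection from
each input image to its stream output.  At each hidden depth a 3×3
convolution carries the previous echo's hidden state into the current
echo, scaled by λ_w = 0.2 (soft weighted view-sharing; direction
earlier→later by default, reversible by config).  Stream outputs are
concatenated into a 7-level UNet: encoder 3×3 stride-2 convolutions with
depths 64, 128, 256, 512, 512, 512, 512; decoder 4×4 stride-2 transposed
convolutions mirroring them, with concatenation skips; a bias-free 1×1
convolution adds an input→output residual.  Every convolution except the
output layer is batch-normalised and therefore carries no bias; stream
and inter-echo convolutions keep biases alongside their normalisation.
**No RNN** is the UNet alone on the concatenated echoes; **Reduced
Parameters** halves every depth except the inputs to the recurrent
portion and the UNet.

Depths the architecture description leaves open were fixed by one hard
constraint: the three reference trainable-parameter counts
(39,808,710 / 35,116,037 / 9,958,246) are treated as the specification
of record, and the depths above reproduce all three *exactly* — the test
suite asserts that.  Two consequences worth
stating: normalisation layers with affine parameters are required (no
bias/depth assignment without them reaches the printed counts), and the
7-level UNet needs slice dimensions divisible by 128 — at its native
256×128 grid the bottleneck is 2×1.  For smaller phantoms
`n_levels_for_grid` truncates the encoder depth list (e.g. 5 levels at
32×32); the halving rule is unaffected.

Normalisation uses batch (per-input) statistics at inference as well as
training.  With the batch-size-1 protocol, running-average statistics
diverge from the per-image statistics the weights are trained against —
in desk-scale runs validation loss visibly exploded after two epochs —
while per-input statistics (instance-norm semantics) are accurate and
still deterministic.

Initialisation: He-normal convolution weights, zero biases, except the
1×1 input residual (zero-initialised) and the output layer bias
(initialised to 40 ms).  Starting the output in the tissue T2 range
instead of at zero removes a long scale-finding phase that a
few-hundred-step desk-scale budget cannot afford; both choices are
ordinary initialisation policy and do not change what the network can
express.

## Training protocol

Adam, learning rate 0.001, batch size 1.  Signals are scaled per slice so
the middle 95 % of pixel values (2.5th–97.5th percentile, computed
jointly over the slice's four echo images so relative decay is preserved;
"per slice" does not say per echo, and the joint reading is the one that
leaves T2 untouched) spans [0, 500] for knee and spine, [0, 100] for the
hip.  Augmentation applies one random rigid transform — translation
within ±10 px (scaled down on small phantoms), rotation within ±5° —
identically to all four echo images, the target map (bilinear) and the
ROI mask (nearest, zero-filled outside).  Training stops when validation
loss has not improved for 10 epochs and returns the best-validation
checkpoint, not the last.

## Evaluation

ROI NRMSE `‖T2−T̂2‖₂,φ (‖T2‖₂,φ)⁻¹`; T2-value equivalents (NRMSE × mean
ROI T2, in ms); Pearson r pooled over ROI pixels per scan (two-sided p);
Bland–Altman bias ± 1.96 s.d. limits of agreement on compartment means.
Texture retention: maps are clipped to [0, 1.5·x_h] and uniformly
quantised to 32 gray levels (both package defaults — the reference
framework does not state them), symmetric co-occurrence counts are
accumulated at d = 1, θ ∈ {0°, 45°, 90°, 135°} over pixel pairs whose
*both* members lie in the ROI (mask edges contribute nothing), pooled
across the slices of a scan; contrast, dissimilarity, homogeneity, ASM
and energy are averaged over the four offsets.  Agreement between
truth-derived and prediction-derived metrics across scans uses the
consistency ICC for a two-way mixed-effects, single-measurement design,
ICC(3,1) = (MS_rows − MS_err)/(MS_rows + MS_err), with F-based 95 % CI
and p; the absolute-agreement form is available behind a flag
(`form="agreement"`), consistency being the default reading of "two-way
mixed effects, single rater".

## Desk-scale validation experiments

`accelt2.experiments` fixes the two study-condition experiments the
acceptance machinery runs.  `zero_fill_r_trend`: ten knee phantoms
(64×64×8), undersampled at R = 2, 4, 8 and fitted with no reconstruction;
mean ROI NRMSE must be non-decreasing in R.  `smoke_training_benchmark`:
sixteen training phantoms (32×32×8, two slices each), four validation and
four held-out test phantoms at R = 4; a Reduced-Parameters network
(encoder truncated to 5 levels for the 32×32 slices) trained for at most
10 epochs with weights (1, 100, 1, 0) must reach a lower mean ROI NRMSE
on the held-out phantoms than the zero-fill baseline.  These problem
sizes keep each experiment to minutes on a single CPU while preserving
the qualitative behaviour being tested; they are not expected to
reproduce GPU-scale reconstruction quality.

## Known limitations

* The phantom family is geometrically simple; texture inside the ROI
  comes from lesions and noise only.
* No Rician-bias-corrected fitting; T2 estimates at very low SNR are
  biased upward.
* Echo-sharing reduces apparent decay for shared lines, which is exactly
  the artifact the trend experiment measures, but no parallel-imaging or
  multi-coil effects are simulated.
* The pretrained feature extractor is optional and not bundled; the
  seeded random stack is the default, so feature-loss *values* are not
  comparable to VGG-based numbers, only their behaviour is.
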