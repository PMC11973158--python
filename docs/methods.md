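# Methods

`fourierpd` implements complex-valued unrolled primal-dual reconstruction of
undersampled single-channel Cartesian MRI, together with the PRF-shift
thermometry chain needed to judge whether an accelerated acquisition still
yields usable temperature maps. This note records the models, the defaults
and the design choices that were genuinely open.

## Problem setting

MR-guided hyperthermia monitors tumour temperature with dynamic gradient-echo
imaging. The water proton resonance frequency shifts linearly with
temperature, so the image phase accrued over the echo time TE changes by

    dphi = gamma * alpha * B0 * TE * dT        [rad]

per dT degrees Celsius, with gamma the proton gyromagnetic ratio
(2*pi*42.577e6 rad/s/T), alpha the PRF sensitivity (default -0.01 ppm/degC,
tissue independent, configurable) and B0 the field strength. Acquisitions
are slow; acquiring only a fraction f of k-space accelerates scanning by
1/f but violates Nyquist, and the naive zero-filled reconstruction is
blurred and aliased in both magnitude and — critically for thermometry —
phase. The package reconstructs complex images from undersampled k-space
with complex-valued neural networks and evaluates the temperature maps they
produce.

## Undersampling model

Masks are binary Cartesian patterns over a centered k-space grid (DC at
`(rows//2, cols//2)`, 0-based). All transforms are centered and
orthonormally scaled, so Parseval holds exactly and the adjoint of the
forward FFT is its inverse — which makes the data-consistency and
zero-filled identities exact rather than approximate.

* `varden1d`: full readout lines along the phase-encoding direction;
  exactly `round(f * rows)` lines (round half away from zero), of which a
  contiguous block of 8 centre lines is always acquired; the rest are drawn
  without replacement with probability proportional to a 1D normal density
  centred on DC. The density's sigma is not dictated by the sampling-mask
  literature's common form; we use `rows/6` so that +-3 sigma spans the
  grid.
* `varden2d`: individual points; a fully sampled central "disc" of exactly
  `round(0.025 * N)` points nearest DC (ties at the boundary radius broken
  by flat index so the count is exact), remainder drawn from a 2D normal
  density with sigma `max(shape)/6`.

Counts are exact by construction and asserted for every mask. Theoretical
acceleration is defined as `1/f` (4 at 25%, 10 at 10%), independent of
integer rounding of the point budget.

Whether one mask is shared by all frames of an experiment or re-drawn per
acquisition is a modelling choice. Static training pairs use a fixed mask
per sample (drawn from a small pool); the dynamic heated series re-draws
the mask per time point, since each time point of a dynamic protocol is a
separate acquisition. This matters: with a single mask and an otherwise
static object, zero-filled aliasing ghosts are identical in the reference
and heated frames and cancel in the phase difference, flattering the
zero-filled baseline in a way real dynamic data do not.

## Complex-valued building blocks

A complex convolution with kernel `w = w_r + i w_i` on input
`x = x_r + i x_i` expands into four real convolutions,

    C_r = w_r * x_r - w_i * x_i,   C_i = w_i * x_r + w_r * x_i,

equivalently the real block matrix `[[w_r, -w_i], [w_i, w_r]]` acting on
`(x_r, x_i)`. This preserves the complex-algebraic structure that feeding
real/imaginary parts as independent channels to a real network destroys.

The nonlinearity is the split rectifier (ReLU on real and imaginary parts
independently). The original architecture description names no activation;
the split form is the common choice in this model family and is exposed as
configuration. Kernels are initialized from a zero-mean normal with
variance `1/(2 * fan_in)` per component — half the real-valued He rule, so
the complex output variance matches the real convention. Biases are
complex (two real parameters per channel), default on.

The training loss is the complex L1 / mean absolute error

    f(y, yhat) = mean_over_voxels(|y_r - yhat_r| + |y_i - yhat_i|),

averaged over every voxel of every sample so the scale is resolution
independent.

Because no automatic-differentiation framework is part of the package's
dependency set, `fourierpd.autodiff` provides a minimal float64
reverse-mode engine purpose-built for these networks: im2col convolution,
split ReLU, channel concat/slice, 2x average pooling and nearest-neighbour
upsampling, and a differentiable centered FFT whose reverse-mode rule is
its adjoint (the inverse centered FFT) applied to the complex cotangent —
exact because the transform is unitary and complex-linear. Adam is
implemented alongside.

## Unrolled architectures

Both models unroll `n_iterations` learned primal-dual stages with unshared
weights. State is a primal memory of `n_primal` complex images and a dual
memory of `n_dual` complex k-space grids. Per iteration:

1. dual update: concat(dual memory, FFT of the second primal channel,
   measured k-space) -> complex conv block -> residual add;
2. primal update: concat(primal memory, inverse FFT of the first dual
   channel) -> complex conv block (Fourier-PDNet) or complex UNet
   (Fourier-PDUNet) -> residual add.

The primal memory initializes to the zero-filled reconstruction replicated
across channels, the dual memory to zeros, and the output is the first
primal channel. With every weight zero the network is therefore exactly
the identity on the zero-filled image — a property the tests pin down —
and the final conv layer of each block is initialized 10x smaller than the
rest so an untrained network starts near that identity while gradients
still reach every parameter (a hard zero init would stop gradient flow).
A 1x1 output head mapping the primal memory to one channel was considered
and rejected: it would break the zero-weight identity and adds nothing at
these scales.

Iteration count, channel and filter counts are not dictated by the source
architecture description; defaults follow the learned primal-dual lineage
(10 iterations, 5 primal / 5 dual channels, 32 filters, 3x3 kernels, three
conv layers per block, UNet depth 3). Desk-scale configurations (3
iterations, 8 filters) are used throughout the tests; parameter counts are
deterministic functions of the config and regression-pinned.

## Training and inference

Training minimizes the complex L1 loss between the *backbone* output and
the fully sampled target — data consistency is not applied during training.
At inference the backbone output passes through data consistency:

    k_out = mask * measured + (1 - mask) * FFT(prediction);  out = iFFT(k_out),

which restores the acquired samples verbatim (sup-norm residual at machine
precision) and is idempotent. Unrolled networks are scale sensitive and no
normalization is dictated, so each sample is scaled by the magnitude peak
of its zero-filled reconstruction before the network and unscaled after.

The reference optimization recipe is Adam at initial rate 1e-4 decayed by
10 after every 50 epochs (betas 0.9/0.999, eps 1e-9, batch size 1, 100
epochs); it is kept as the default `TrainConfig` and its schedule is
asserted in tests. Desk-scale runs use `TrainConfig.desk_scale()` (lr 1e-3,
tens of epochs): at a few hundred optimization steps the reference rate has
not moved a freshly initialized network far enough to be informative, and
the larger rate is stable at these sizes. When a validation set is given,
the best-validation-loss weights are kept.

## Thermometry

The phase difference between a heated frame `I_H` and the reference `I_ref`
is computed from the complex product `conj(I_ref) * I_H` via the
four-quadrant arctangent of Im/Re — the printed single-argument arctan of
that ratio loses the quadrant, and the complex construction the formula
encodes implies the four-quadrant form. The result is the principal value
in (-pi, pi] without unwrapping the individual images; shifts beyond pi
wrap (documented and tested). Voxels with zero magnitude in both frames
get dphi = 0 and are flagged in a validity mask. Temperature follows as
`dT = dphi / (gamma * alpha * 1e-6 * B0 * TE)`; the reference frame is
time point 0 of a series.

Accuracy of a temperature-map series x against y is the scaled mean of
squared voxel-and-time differences

    E_T(x, y) = 100 / (V * tau) * sum_t sum_v (dT_x - dT_y)^2,

optionally restricted to an ROI, implemented exactly as printed. Because
published values in this problem area are usually quoted in degrees
Celsius, a companion `rms_temperature_error` (sqrt of the mean squared
difference, in degC) is exposed alongside; the two are monotone transforms
of each other, so orderings agree. Which of the two a given external table
reports is not always decidable; both are first-class here.

## Synthetic phantoms: what they emulate, and what not

The generator emulates single-channel 2D FLASH gradient-echo images at
1.5 T with TE 4.76 or 19.1 ms (TE is a parameter; nothing pins which echo
feeds thermometry, so the longer echo — more phase per degC — is the
default) and dynamic series of 2-17 time points:

* magnitude: a large body ellipse plus random tissue ellipses, clipped to
  `magnitude_range` (default floor 0.15 inside the body for heated-series
  experiments: PRF thermometry is undefined where there is no signal, and
  tumour ROIs are tissue with signal);
* phase: a random polynomial field (order 2 by default) scaled into
  0.9*(-pi, pi], emulating smooth coil/susceptibility phase; the reference
  frame never wraps but heated frames may, and the generator deliberately
  does not pre-unwrap;
* heating: a Gaussian hotspot whose peak ramps linearly across time points
  (profile configurable per frame), applied as the exact PRF phase factor;
* noise: i.i.d. circular complex Gaussian in image space (equivalent to
  k-space noise under the orthonormal FFT), fresh per frame.

Not emulated: B0 drift, motion, multi-coil sensitivities, non-Cartesian
trajectories. Passing tests on these phantoms therefore demonstrate the
algorithmic properties (exact data consistency, correct PRF inversion,
artifact-removal capability) but not clinical robustness to drift, motion
or coil effects.

## The desk-scale study

`fourierpd.experiments.run_small_study` freezes one CPU-sized end-to-end
experiment (shared by the test suite and `scripts/acceptance.py`): 8
phantoms at 64^2, 1D Varden 25% with a 4-mask training pool,
Fourier-PDNet with 3 iterations / 8 filters trained 100 epochs at lr 1e-3
(800 steps, a few minutes on one CPU), then a held-out heated series (4
time points, 6 degC peak, per-time-point masks unseen in training),
scored by magnitude SSIM and by E_T full-volume and in the hotspot ROI
(hotspot above 10% of peak). The problem sizes are chosen so the full
study runs in minutes while leaving a clear margin between the zero-filled
baseline and the reconstruction.

## Metrics

SSIM uses the standard local-window convention: 7x7 uniform window,
sample-covariance normalization, mean over the valid interior, with
`C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`; it matches the scikit-image
implementation to 1e-6 and a "global" whole-image-moment mode is provided
for literal-formula checks. NRMSE is RMSE divided by the RMS of the
reference (first argument). UIQI is the product of correlation, luminance
and contrast terms; one printed variant of its moment definitions carries a
1/(M+N-1) normalizer, which cancels algebraically in the product, so the
"m_plus_n" and conventional "sample" (1/(MN-1)) normalizers return the same
Q — both are exposed, and the moments themselves differ. Complex images are
scored per
channel: magnitude min-max scaled to L = 1 (the ground truth's scaling
applied to both images), phase mapped to [0, 2*pi) with L = 2*pi; no
dynamic-range convention is dictated for phase, so this choice is
documented rather than inherited.

## Numerical choices and degenerate inputs

* float64 throughout the autodiff engine; the zero-weight identity and
  data-consistency residuals are asserted at 1e-12 or exactly.
* mask counts use round-half-away-from-zero; `fraction = 0` is rejected.
* `phase_difference` defines dphi = 0 with a validity flag where both
  numerator and denominator vanish; `nrmse` raises on an identically zero
  reference; `uiqi` raises when both images are constant.
* UIQI's luminance ratio 2*mx*my/(mx^2 + my^2) is 0/0 when both means
  vanish; its matched-luminance limit is 1, and means below 1e-12 of the
  image scale (floating cancellation after mean subtraction) are treated
  as zero so the ratio does not pick up the sign of round-off residues.
* training aborts with diagnostics on a non-finite loss; empty datasets
  are rejected.
* per-sample normalization falls back to scale 1 when the zero-filled
  image is identically zero.

## Known limitations

* Single channel, single slice, Cartesian only; no parallel imaging.
* The desk-scale networks are far smaller than a clinically trained model;
  the study demonstrates orderings (reconstruction better than
  zero-filled), not absolute clinical accuracy.
* The numpy autodiff engine is CPU-bound and sized for 64^2-256^2 images,
  not for large-scale training.
* Phase-image fidelity remains the limiting factor for temperature
  accuracy, as expected for this model family.
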