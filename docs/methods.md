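# Methods

`speckleflow` simulates high-speed defocused-speckle recordings of a flow
phantom — an artificial artery embedded at 0–10 mm depth in scattering
tissue — and analyses them two ways: a 3D convolutional network that
classifies the flow state (zero / low / medium / high) from raw video, and a
classical single-point-calibrated laser speckle contrast analysis (LASCA)
baseline whose cross-depth failure the pipeline reproduces.

## Speckle synthesis

A fully developed speckle field is drawn in the Fourier domain: a
unit-variance circular complex Gaussian white field is multiplied by a
circular pupil of radius `grain_radius` (as a fraction of the Nyquist
radius) and inverse-transformed. The result is exactly circular-Gaussian,
so its intensity is negative-exponential with unit contrast, and its grain
size scales as 1/`grain_radius`. Normalisation divides by the analytic RMS
of the filtered noise, `sqrt(2*sum(mask)/N)`, so the expected mean intensity
is exactly 1 without distorting the marginal distribution. This replaces
numerical evaluation of the free-space diffraction integral; the statistics
are the same and it is orders of magnitude faster.

## Flow-to-dynamics mapping

The physical rig relates valve opening to velocity by volumetric
measurement; the simulator instead needs an explicit mapping from velocity to
speckle dynamics. We use a single-parameter model: the field decorrelation
time is `tau_c = decorrelation_scale / velocity`, and between time steps
`dt` the complex field evolves by a stationary AR(1) step

    A' = rho * A + sqrt(1 - rho^2) * eps,   rho = exp(-v * dt / k_v),

with `eps` an independent field of the same distribution. The default
`decorrelation_scale` k_v = 11/60 cm makes the low-flow midpoint of a 3 mm
vessel (5.5 cm/s) decorrelate with tau_c = 10 frame intervals at 300
frames/s, so the four condition midpoints span near-static to
sub-frame-interval decorrelation.

Pulsation modulates the instantaneous velocity as a raised sine,
`v(t) = v0 * (1 + m sin(2 pi f t))` with f = 1 Hz and m = 0.3 by default,
and additionally translates the whole frame by up to
`translation_amplitude` = 0.5 px at the same frequency, emulating
mechanical coupling of the pulse emulator to the rig. Zero-flow recordings
keep the translation and sensor noise, so the zero class is not a constant
video.

## Rendering and the depth model

Each output frame integrates `exposure_substeps` = 4 field states spanning
the full inter-frame interval (a 100% exposure duty cycle, the simplest
assumption when the true exposure time is unknown). The exposure average is mixed with a frozen static
speckle field in proportion `static_fraction`, blurred by a Gaussian PSF of
width `blur_sigma`, translated, corrupted by additive Gaussian sensor noise
(0.5 gray levels), scaled by a fixed gain and quantised to 8 bits.

Depth degrades the recording through two monotone knobs chosen to reproduce
the qualitative contrast loss with depth while keeping all classes
learnable:

| depth (mm) | static_fraction | blur_sigma (px) |
|-----------:|----------------:|----------------:|
| 0          | 0.2             | 0.0             |
| 5          | 0.5             | 1.0             |
| 10         | 0.7             | 2.0             |

The quantisation gain maps mean intensity to gray level 50. With a
unit-contrast exponential intensity this leaves <1% of pixels saturated, so
rendered-frame contrast stays within a few percent of the field contrast; a
higher set point (e.g. mean at 100) would clip ~8% of pixels and compress
contrast by ~16%, distorting the very statistic LASCA measures.

## What the generator emulates — and what it does not

It reproduces: the recording geometry (224x224 at 300 fps for 33 s at full
scale), the four velocity ranges per vessel diameter, 1 Hz pulsatility,
velocity-dependent temporal decorrelation and exposure-driven contrast
loss, and depth-dependent static scattering and blur. It does **not**
model: physical light propagation through layered tissue, the intralipid
hydraulics, skull-like layers, speckle boiling vs. translation regimes, or
any depth-dependent change in scattering path length beyond the two knobs
above. Consequently a passing test shows the *analysis pipeline* behaves
correctly on data with the right statistical structure, not that the
classifier would reach the same accuracy on real recordings.

One knock-on effect: because contrast decreases monotonically with depth
here, a 10 mm calibration applied at 5 mm *under*-estimates velocity. A real
defocused rig, where scattering path lengths change with depth in more
complicated ways, can err in the opposite direction; the magnitude of the
breakdown (~70% mean error vs ~12% same-depth) is the robust feature, the
sign is a property of the monotone depth model.

## Preprocessing

Frames are divided by 255 exactly, cut into 64-frame chunks with stride 32
(trailing partial windows dropped; a 9900-frame video yields 308 chunks),
and replicated to three identical channels. The last-recorded video of
every (diameter, depth, condition) cell is held out for testing —
leakage control is at video level, so overlapping chunks never straddle the
train/test boundary — and 10% of the remaining chunks, drawn uniformly
without stratification, form the validation set.

## Classifier

The network follows the conv–batchnorm–ReLU block pattern of efficient 3D
video classifiers: a stem Conv3D (kernel 3x3x3, stride 1, padding 1), a
stack of blocks whose channel count grows while 2x2x2 max-pooling halves
all dimensions, global average pooling and a dense softmax head. The
full-scale profile uses stem 24 with schedule 24→48→96→192; the desk-scale
profile (stem 8, schedule 8→16→32 on 3x64x64x64 inputs) trains on one CPU
in minutes. We implement the generic
block stack rather than the full published X3D_M topology with its expansion
factors; the stack is configurable so a faithful X3D_M could be swapped in.

Because no GPU framework is assumed, the engine is written directly in
numpy: convolutions are im2col slice-copies plus one GEMM per sample (the
input gradient of the stem is skipped — nothing consumes it), batchnorm and
ReLU operate in place, and training uses mini-batch Adam (lr 1e-3, batch 8)
on categorical cross-entropy `L = -sum_i t_i log p_i` with probabilities
floored at 1e-12. Checkpointing keeps the best-validation-accuracy epoch
(ties to the later epoch). After restoring the best weights, batch-norm
running statistics are re-estimated in one pass over the training chunks
(momentum 1/i), since on small datasets the training-time moving averages
trail the weights badly enough to corrupt eval-mode predictions.
Half-precision training is available but off by default so desk runs are
bit-reproducible.

## LASCA baseline

Spatial speckle contrast K = sigma/mu (population standard deviation) is
computed on non-overlapping 7x7 windows, averaged over windows and frames.
Single-point calibration takes one reference recording with known velocity
V_ref and sets A = V_ref * K_ref^2; estimates are V = A / K^2. The
cross-depth experiment calibrates on a medium-flow recording at 10 mm and
applies the constant at 10 mm (same depth) and 5 mm: same-depth recovery is
good because the test recordings share the calibration velocity and
geometry, while across depths the depth-dependent static fraction and blur
shift K for reasons unrelated to velocity and the estimate breaks down —
the central LASCA limitation the deep-learning approach avoids.

## Problem sizes and numerical choices

Tests and the acceptance script run the desk-scale profile: 64x64-pixel
frames, 0.16–1 s videos, single-cell simulation grids, and 12 training
epochs — sizes at which every stage completes on one CPU while all the
qualitative properties (speckle statistics, monotonicities, LASCA
behaviour, learnability well above chance) are already stable. Notable
numerical choices: analytic field normalisation (above); pooling gradients
split equally among tied maxima; zero-denominator precision/recall/F1
reported as 0 with an explicit degeneracy flag; majority-vote ties at video
level resolved toward the lower-flow class (the clinically conservative
choice); per-video and per-stage seeds derived from the master seed by
SHA-256 so reproducibility is independent of generation order.

## Known limitations

* The velocity→tau_c mapping and the depth knobs are plausible conventions,
  not fits to the physical rig; absolute contrast values and error
  magnitudes should be read as qualitative.
* The desk-scale classifier experiment uses condition-midpoint velocities
  (maximally separated classes); accuracy on uniformly drawn velocities
  within each range is lower near range boundaries.
* Batch-norm statistics are recalibrated on training data only; under
  strong train/test distribution shift (not present in the synthetic
  datasets) that choice matters.
* The 8-bit container caps the usable dynamic range; saturated pixels are
  clipped, not modelled as sensor blooming.
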