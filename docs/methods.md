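# Methods

## Model

The package implements division-based correction of multiplicative
intensity inhomogeneity in T1-weighted brain MRI. The acquired image is
modeled voxelwise as `a(r) = u(r) · b(r)` with `u` the unbiased image
and `b` a strictly positive, smooth, low-spatial-frequency field. In log
space the field is additive and signed, so the estimator is a 3D U-Net
`f` trained to regress `log b̂ = f(a)` from the normalized image; the
correction is `û = a / exp(log b̂)` (denominator clamped at
`eps = 1e-6` on the normalized scale so background zeros cannot produce
infinities).

Assumptions inherited from this model: the corruption is purely
multiplicative and smooth relative to anatomy; noise is small compared
with tissue contrast; a brain mask is available to keep zero-background
voxels out of all losses and metrics.

## Losses

Both supervision terms are masked mean squared errors in *linear*
intensity space:

* field term: `L_a = (1/N) Σ_mask (exp(log b̂) − b)²`
* corrected-image term: `L_b = (1/N) Σ_mask (a / exp(log b̂) − u)²`
* total: `L = L_a + L_b`.

`N` is the number of masked voxels, so the losses are invariant to mask
size at fixed per-voxel residuals and to every voxel outside the mask.
A pure log-space variant of each term is exposed (`space="log"`) but is
not the default. Gradients of `L` with respect to the predicted log
field are computed in closed form and seed hand-derived backpropagation
through the network; the full chain is verified against central finite
differences in float64.

By default the post-hoc smoothing step sits *outside* the training loss
(the loss sees the raw exponentiated prediction). With
`smoothing_in_loss=True` the Gaussian regularizer is applied to
`exp(log b̂)` before both loss terms; it is implemented as an explicit
per-axis linear operator so its adjoint (the transpose) is exact in the
backward pass. The slicewise B-spline fit is deliberately kept out of
the differentiable path and requesting it there is an error.

## Network

A generic 3D encoder–decoder: `levels` resolution stages, each two
(3×3×3 convolution → instance normalization → leaky ReLU, slope 0.01)
layers; 2×2×2 max pooling between encoder stages; stride-2 transpose
convolutions (3×3×3, output padding 1) with channel-concatenating skip
connections in the decoder; a final linear 1×1×1 projection with **no
output nonlinearity**, because a log field is signed. Channel width
doubles per stage from `base_channels`. Input sides must be divisible by
`2^(levels−1)`.

The 1×1×1 head is zero-initialized, so an untrained network predicts
`log b = 0` — the identity field. This is a standard residual-style
prior for field regression: the model starts from "no correction" and
learns deviations, which also makes the first optimization steps
well-scaled. All other convolutions use He initialization from a seeded
generator; identical configurations (including seed) produce
bit-identical parameters.

Because no deep-learning framework is a dependency, the layers, their
backward passes and Adam are written directly on NumPy arrays
(`nn.py`); convolutions are evaluated as 27 shifted GEMMs, which keeps
peak memory low and is fast enough for desk-scale volumes on one CPU.

## Training

Adam with learning rate 1e-4 (the published protocol's value), batch
size 1, gradients averaged over a batch when larger. Model selection
keeps the weights of the epoch with the lowest validation total loss.
Dataset splitting is a seeded shuffle with floor-then-largest-remainder
size allocation (100 items at 90/5/5% give exactly 90/5/5). Epoch count
and batch size are not reported in the original protocol, so they are
configuration with desk-scale defaults (10 epochs, batch 1).

All randomness (initialization, shuffling, generators) flows from
explicit seeds; `(seed, config, data)` fully determine the training
history. Checkpoints store weights, best-on-validation weights, Adam
moments and the shuffling RNG state, versioned and written atomically;
a resumed run reproduces the uninterrupted trajectory bit for bit.

The single-sample overfit diagnostic (drive the loss on one 32³ sample
below 5% of its initial value in 300 steps) runs at Adam's canonical
1e-3 step size rather than the protocol's 1e-4: it asks whether the
architecture and gradients can memorize one field quickly, not whether
the conservative full-protocol rate converges within an arbitrary
budget. At 1e-4 the loss is still descending monotonically after 300
steps (ratio ≈ 0.10); at 1e-3 it reaches ≈ 0.001.

## Preprocessing

The fixed chain mirrors common large-corpus practice: trilinear
resampling to 2 mm isotropic (masks nearest-neighbour), centered
pad/crop to 128³ (zeros, floor/ceil split per axis), then min-max
normalization `clip(X / p99(X), 0, 1)` where `p99` is the 99th
percentile (linear interpolation) over *all* voxels — normalization
precedes masking, since the mask is derived from the normalized image.
Output resampling shapes use round-half-away-from-zero on
physical-extent arithmetic. Every step records its parameters so a
predicted field can be mapped back: inverse pad/crop (cropped margins
refilled by edge replication — harmless for a smooth field) followed by
trilinear resampling onto the native lattice; correction is then
performed at native resolution. Desk-scale work skips the 2 mm/128³
convention and uses the native 48³ grid directly; both are exposed.

Brain masking is threshold → largest 6-connected component →
morphological hole fill. The threshold is the *lowest* cut of a
four-class multi-Otsu: a T1w head histogram is multimodal (background,
CSF, GM, WM) and a binary Otsu tends to cut within the head, excluding
CSF; the four-class variant separates background from everything else.
Images with too few distinct gray levels fall back to three-class, then
binary Otsu. The mask only gates losses and metrics, so this is
deliberately simpler than clinical skull stripping.

## Field smoothing variants

* `NS` — identity.
* `G` — separable convolution with a truncated Gaussian, kernel 19
  voxels per axis, σ = 3 voxels, renormalized to sum 1, reflective
  boundaries (avoids edge darkening of a multiplicative field).
  Constants are exact fixed points.
* `B` — per-slice multilevel least-squares approximation with clamped
  uniform cubic B-splines, 5 levels: level 1 fits a single-span tensor
  mesh, each later level doubles the span count per axis and fits the
  residual of the accumulated reconstruction. Clamped knot vectors keep
  constants inside every level's space and make the spaces nested under
  span doubling, so a surface synthesized at the finest level is
  recovered exactly (up to conditioning). The slicing axis defaults to
  the third (axial) and is configurable. Output is clamped at `eps`
  since least-squares approximation can undershoot. The fit is dense
  (all slice voxels enter the normal equations) rather than fitting a
  random subsample of points; this is a known deviation from
  descriptions that subsample, chosen because the field here is dense
  and small.

Smoothing operates on the exponentiated field and is deterministic.

## Synthetic phantoms

The generator emulates the statistical structure the correction model
assumes, not anatomy. A head is three nested ellipsoids on a cubic
lattice (default 48³): WM inside GM inside a CSF shell filling the
support (default semi-axes 0.42/0.40/0.38 of the shape; WM and GM at
0.60 and 0.85 of the support radii). Tissue intensities are
0.15/0.45/0.75 on the normalized scale with within-class Gaussian
jitter (SD 0.02), background exactly 0, and per-seed geometry jitter
(±5% semi-axes, small center shifts) so a dataset is not one head
repeated. Defaults for the jitters were chosen once as what a plausible
test corpus needs (visible texture, inter-subject variation) and are
spec fields, not tuning knobs.

Bias fields are `b = exp(g)` with `g` drawn from one of three families:
Gaussian-filtered white noise (default correlation length ¼ of the
volume side), a random low-order polynomial in normalized coordinates,
or a random coarse B-spline control mesh interpolated up. Each draw is
rescaled so `max |log b|` equals `log_amplitude` (default 0.3, i.e.
fields spanning ≈ [0.74, 1.35] — visible shading that does not destroy
tissue contrast, the regime bias correction targets). The acquired
image is `a = u·b` plus optional additive Gaussian noise (default SD
0.01 on the normalized scale).

What the phantoms do **not** model: real anatomy and partial-volume
mixing, Rician noise statistics, scanner-specific artifacts, and the
particular spatial statistics of fields produced by real coils. Tests
passing on phantoms therefore demonstrate that the estimator recovers
smooth multiplicative corruption under the model's assumptions — not
clinical-grade performance on arbitrary scanners.

## Evaluation

PSNR is `10·log10(R²/MSE)` with MSE over masked voxels and `R` the
masked maximum of the reference; identical images report `inf`. The
masked convention matters: whole-volume PSNR on brain images is
dominated by background zeros, and absolute dB values are not
comparable across conventions. Method comparison uses the two-sided
Wilcoxon signed-rank test on per-case differences — exact for n ≤ 25
via convolution over doubled midranks (equivalent to enumerating all 2^n
sign patterns and valid under ties), normal approximation with
continuity correction above — with Bonferroni adjustment by the number
of method pairs, plus Cohen's d as mean(diff)/SD(diff) (the paired
variant; an exact constant shift has SD 0 and reports a signed
infinity). Percentile case selection returns the case nearest the
linear-interpolation percentile of the score distribution, ties toward
the smaller id. Mean-shift intensity matching adds a constant so the
masked mean of the corrected image equals the reference's (a
multiplicative rescaling variant is exposed); it is an evaluation-time
adjustment and opt-in at the CLI.

## Desk-scale experiment sizes

The canned field-recovery experiment trains a levels-3, 8-channel
network on 64 phantoms (48³, Gaussian-random-field bias with log
amplitude 0.3, noise SD 0.01) for 10 epochs with 8 validation and 16
held-out samples — small enough to run in minutes on one CPU while
still exercising the full pipeline. With these sizes the held-out
median PSNR gain from correction is ≈ 3 dB and the median masked
Pearson correlation between predicted and true log fields is ≈ 0.87;
larger models and corpora improve both, so these numbers are
lower bounds characterizing the miniature setup, not the method's
ceiling.

## Known limitations

* The estimator is trained per-resolution-convention; a checkpoint
  expects inputs preprocessed the way its training data were.
* The B-spline regularizer is slicewise (2D), not a full 3D mesh fit
  with ITK-style control-point bookkeeping.
* No augmentation, learning-rate schedules, mixed precision or
  multi-device support; training is deliberately single-threaded and
  deterministic.
* CPU-only NumPy execution limits practical training to desk-scale
  volumes; inference on full 128³ inputs is fine.
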