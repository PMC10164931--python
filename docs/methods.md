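# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `ivmproc`, in the spirit of a methods supplement.
It states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

All stages operate on `Stack5D`: a five-axis array in canonical
`(t, z, c, y, x)` order with physical calibration (voxel size in µm per
axis, frame interval in seconds). Indices are 0-based, voxel centers sit at
integer indices, and physical position is `index × voxel_size`. One
convention everywhere is deliberate: registration code is where sign and
axis-order bugs hide.

OME-TIFF is the primary on-disk dialect; bare multi-page TIFF is accepted
with a JSON sidecar (`<file>.tif.json`) holding `voxel_size_um`,
`frame_interval_s`, `channel_names` and optionally `axes`. A bare 3D
multi-page file without metadata is refused as ambiguous (the page axis
could be T, Z or C) rather than guessed.

Floating-point intermediates are rescaled to unsigned integers by rounding
half away from zero and clipping to the bit-depth range; clip counts are
logged. The tie rule is a convention choice (the common tool chain does not
state one); half-away-from-zero was picked because it is symmetric and
matches intuition for intensity data. The same rule is used wherever float
results are re-quantized (denoising output, resampled volumes, truncated
median windows with an even voxel count).

## Noise model and variance stabilization

The detector model is `z = α·p + n` with `p ~ Poisson(y)` photons, gain `α`
in ADU/photon, and `n ~ N(μ, σ²)` read noise, so `E[z] = α·y + μ` and
`Var[z] = α²·y + σ²`. The clean phantom stores expected signal in ADU;
corruption draws `p ~ Poisson(signal/α)`, keeping the generator and the
denoiser on one shared parameterization (no double-counting of gain).

The forward generalized Anscombe transform is

    f(z) = (2/α) · sqrt(α·z + (3/8)·α² + σ² − α·μ),

clamped to 0 where the radicand is non-positive. Two inverses are provided:

- `algebraic` — the exact functional inverse on the transform's range.
  Composed with the forward transform it is identity to machine precision,
  but applied to a *denoised* (i.e. averaged) stabilized value it retains a
  small-count bias.
- `exact_unbiased` — the closed-form approximation of the exact unbiased
  inverse for the unit-gain Anscombe transform,
  `I(D) = D²/4 + √(3/2)/4·D⁻¹ − 11/8·D⁻² + 5/8·√(3/2)·D⁻³ − 1/8`,
  generalized to `(α, σ, μ)` by the substitution `z' = (z − μ)/α`,
  `σ' = σ/α` (subtract `σ'²`, rescale by `α`, re-add `μ`). This inverse is
  defined on an estimate of `E[f(z)]` — the quantity a Gaussian-domain
  denoiser outputs — and is *not* unbiased when applied to individual noisy
  draws (Jensen's inequality adds ≈ +0.25 photons at `y = 20`). The test
  suite therefore checks it on the mean of the stabilized draws, its
  designed operating point. It is the pipeline default.

Negative inverse outputs are clipped to 0 and logged.

## Noise-level estimation

`estimate_noise_sigma` is the median absolute deviation of the finest
diagonal (HH) wavelet detail subband (db2), scaled by 1/0.6745. Edges and
smooth structure contribute only sparsely to that subband, so the median
ignores them; the estimator recovers known Gaussian σ within a few percent
on both flat and structured 512² images (tested at σ = 2, 5, 10 ADU) and
returns ~0 on noise-free step edges. For volumes the estimate is computed
once per channel on a tiled mosaic of up to 10 evenly spaced slices
(indices `round(linspace(0, n−1, k))`, `⌈√k⌉` columns, zero-padded last
row); tiling pools more pixels and avoids trusting one unrepresentative
plane. In 2D mode the middle frame is used. Estimating once per channel
(not per chunk) was chosen because chunk-level estimates are noisier and
the noise level of a stack acquired in one session is stationary.

On real Poisson-Gaussian data this estimator reports the *total* local
noise level (Poisson plus Gaussian) around typical intensities, not the
pure Gaussian σ; the gain `α` and offset `μ` must be supplied (defaults
α = 1, μ = 0). This mirrors common practice, where a single estimated σ
parameterizes the GAT; a full (α, σ) estimation from local mean-variance
regression is out of scope.

## Collaborative filter

The Gaussian-domain denoiser is a two-stage patch-grouping
transform-shrinkage filter in the classic block-matching style, written
dimension-agnostically (8×8 patches in 2D, 4×4×4 cubes in 3D):

1. **Hard-threshold stage.** For reference patches on a stride-4 (2D) or
   (2, 4, 4) (3D) grid, the most similar patches inside a bounded search
   window (default 39 px laterally; ±2 slices axially in 3D) are found by
   exhaustive offset search — per offset, the patchwise squared-distance
   field is a box sum of the shifted squared-difference image, so matching
   costs one pass over the data per offset. The best 16 form a group; an
   orthonormal DCT is applied over the patch axes and across the group;
   coefficients below `2.7 × noise_std` are zeroed; the inverse transform's
   patches are aggregated by weighted overlap-add (weight = 1/#surviving
   coefficients).
2. **Wiener stage.** Matching is repeated on the first estimate; groups are
   extracted from both the noisy data and the estimate; the noisy group's
   coefficients are shrunk by the empirical Wiener factor `B²/(B² + σ²)`
   computed from the estimate, and aggregated with weights `1/Σw²`.

The filter is deterministic and is *not* a bit-exact clone of the reference
BM3D/BM4D implementations: thresholds, strides and window sizes are
exposed in `VSTConfig` and the filter backend is pluggable (an `identity`
backend exists for pipeline round-trip diagnostics). The pipeline's
contribution is the composition (estimation → GAT → [0,1] rescale →
filtering → inverse), which is checked end-to-end: with the identity
backend the pipeline reproduces its input within ±1 ADU, and with the real
backend it improves PSNR on every phantom channel.

Chunking: volumes are filtered in chunks of 10 frames overlapping 5 at
each extremity. Each frame is *owned* by exactly one chunk — the chunk
whose center is nearest, ties to the earlier chunk, candidates restricted
to chunks containing the frame — so the keep-ranges partition the frame
axis exactly and merging needs no blending. Ownership-based merging was
chosen over overlap blending because it is deterministic and
partition-testable; the overlap still buys each owned frame a full
temporal/axial context.

## Median-3D baseline

`median3d` replaces each voxel with the median of its `(2r+1)³`
neighborhood within one (t, c), default r = 2 per axis (a 5×5×5 window,
the common FIJI semantics for "radius 2"; a median filter has no σ
parameter, so a literal σ is read as the per-axis radius). Borders use
neighborhood truncation — the median of in-bounds voxels only — rather
than padded values; the interior is computed by `scipy.ndimage` and the
border shell recomputed exactly with truncated windows. Truncated windows
with an even voxel count yield half-integer medians; on integer stacks
these are rounded half away from zero.

## Drift correction

The registration channel is the float sum of all detection channels
(order-invariant), contrast-stretched per frame by clipping 0.5% of pixels
at each histogram tail (a symmetric reading of "1% saturated pixels") and
mapping linearly to the full bit-depth range, then requantized. Summing
channels maximizes detectable features: single channels of sparse
fluorescent structures often lack enough keypoints for stable matching.

Translation estimation uses multi-scale SIFT (scikit-image): initial blur
1.5 px, 3 scale steps per octave, octave count bounded so the coarsest
level stays ≥ 64 px; frames larger than 512 px are downscaled for
estimation and the shifts rescaled. Matches pass a 0.92 ratio test with
cross-checking; the translation is fitted by consensus — every match
proposes a candidate shift, the candidate with the most inliers within
ε = 3 px wins, and the inlier displacements are averaged (sub-pixel). A
pair with fewer than 7 inliers falls back to a zero shift and is flagged,
never aborting a batch series. Both sequential pairwise estimation
(composed to frame 0) and fixed-reference matching are provided; which one
the original workflow used is not stated, so both ship, sequential by
default. Sub-pixel pair errors accumulate slowly under sequential
composition (tested: < 0.6 px over an 8-frame drifting series, individual
pairs exact for integer shifts and < 0.25 px for half-pixel shifts).

Shift application is bilinear with zero fill; the estimated series maps
each frame into the reference (frame 0) coordinate system, and the
registration channel is discarded from the output.

## Rigid serial registration

`fit_rigid` is the closed-form least-squares solution: center both point
sets, SVD of the cross-covariance, determinant-corrected rotation (so the
result is always a proper rotation, never a reflection), translation from
the centroids. Degenerate configurations (< 3 active pairs, collinear
points) are rejected. Landmarks live in physical µm, (x, y, z) per point,
in a headerless CSV compatible with BigWarp's export
(`name, active, moving xyz, fixed xyz`).

The fitted transform maps moving → reference coordinates; resampling pulls
through the inverse with trilinear interpolation at reference voxel
centers expressed in physical coordinates, so anisotropic voxels are
handled without special cases, and out-of-volume samples are 0. Trilinear
(not spline) interpolation keeps intensities non-negative and bounded.
Pure rotation + translation is deliberate — similarity and deformable
transforms can absorb genuine biological size/shape changes (tissue
shrinkage after injury), which serial imaging exists to measure.

Replicate alignment for ground-truth generation uses true normalized
cross-correlation over the overlap region at every candidate shift
(computed with zero-padded FFT correlations of the images, their squares
and their support masks), followed by per-axis quadratic peak refinement.
Plain circular FFT correlation is biased toward small shifts when the
displacement is a sizeable fraction of a short axis (the z extent of a
typical stack); the overlap-normalized form is not (tested: < 0.05 voxel
error at integer shifts of 2–3 voxels on a 12-slice volume).

## Ground truth and benchmark

Ground truth is the per-voxel arithmetic mean of aligned replicates,
quantized to the input bit depth. For independent zero-mean noise this
gains `10·log₁₀(n)` dB PSNR over a single replicate (verified at n = 25 to
within 0.5 dB, including quantization effects).

PSNR uses `peak = max(reference slice)` by default, matching the behavior
class of per-slice measurement tools; a fixed-peak mode (`2^bits − 1`) is
available since the convention is not standardized. Metrics are computed
per slice, per channel, per time point; the benchmark emits one row per
(method, channel, time point, slice), so a 25-time-point, 45-slice
validation set yields 1,125 rows per channel per method. Identical images
are flagged with infinite PSNR and excluded from summary means.

## The phantom generator

The generator emulates the structure of a three-channel kidney recording:

- **endothelium** — flat-topped vessel filaments: 3D random walks dilated
  to a capillary radius of 5 px (~6 µm diameter at the default 0.58 µm/px)
  with anisotropic z extent, rim softened by a 1-px Gaussian (a PSF
  stand-in). Amplitude 350 ADU.
- **tubules** — hollow tube walls (binary shell of half-thickness 2.5 px
  at radius `min(y, x)/8`, softened 1 px; amplitude 250 ADU) plus bright
  well-separated Gaussian puncta (σ 1.3 px, amplitude 600 ADU, minimum
  separation 7 px) emulating lysosomes — deliberately countable by
  thresholded connected components for oracle tests.
- **capsule** — thin oriented fibrils confined to the top ~15% of slices,
  amplitude 120 ADU: the weakest, lowest-SNR channel, like a
  second-harmonic collagen signal.

Background is 25 ADU; structure counts scale with lateral area (12
filaments, 4 tubes, 30 puncta, 20 fibrils at 256²) so feature density is
resolution-independent. The default noise model is α = 4 ADU/photon,
σ = 10 ADU, μ = 0 — the high-gain, low-power regime in which replicate
validation experiments are deliberately acquired. These amplitudes and
noise levels were fixed so that the phantom reproduces the qualitative
raw-PSNR ordering of such data (bright endothelium > tubules > weak
capsule) and its method ranking: in this regime the Median-3D filter's
structural bias (it erodes curved rims) is smaller than the raw noise
error, so it modestly beats raw data everywhere while variance-stabilized
filtering wins clearly — flat-topped structures wider than the median
window and noise-dominated MSE are exactly what real tubules and vessels
provide. Thin-ridge structures at low noise would invert that ranking,
which is a property of the regime, not of the filters.

What the phantom does **not** model: optical point-spread convolution and
depth-dependent scattering, vascular flow and motion during a frame,
photobleaching (except as an optional mono-exponential decay channel for
wash-out experiments), detector saturation, and spatially correlated
noise. Passing tests therefore demonstrate algorithmic correctness under
the stated noise model, not photorealism.

Determinism: every generator is a pure function of (spec, seed); child
seeds for replicates and stages derive from the global seed through
`numpy.random.SeedSequence` with fixed stage tags.

## Problem sizes used by the test suite

The default phantom geometry mirrors a full validation set
(25 × 45 × 3 × 256 × 256), but the test suite and benchmark fixtures run
reduced instances chosen as the package's own desk-scale conditions: the
row-count benchmark keeps the full 25 time points × 45 slices at 32² so
the complete three-method run stays tractable; the quality-ordering
benchmark uses 6 replicates of a 16 × 96 × 96 volume, where structure
sizes in pixels match real data at full lateral sampling. Monte-Carlo
checks use 10⁴–10⁶ draws as stated in each test.

## Known limitations

- The collaborative filter trades some denoising quality for portability
  and speed; it is not bit-compatible with reference BM3D/BM4D and its
  PSNR numbers should be compared within this package, not against
  published BM3D figures.
- `estimate_noise_sigma` conflates Poisson and Gaussian contributions on
  raw data (see above); supplying the true gain improves stabilization.
- SIFT-based estimation needs textured frames; on near-empty frames the
  flagged zero-shift fallback keeps batches running but leaves those
  frames uncorrected.
- Rigid registration cannot model tissue shrinkage by construction; the
  residual report makes the misfit visible instead of hiding it.
- The OME reader covers the common TZCYX layouts written by this package
  and by FIJI/Bioformats exports; exotic modulo/plane-interleaved layouts
  need an explicit axis hint.
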