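# ivmproc

A scriptable processing toolbox for intravital 2-photon microscopy of the
kidney and other abdominal organs. Live-tissue recordings made at low laser
power and high detector gain are corrupted by mixed Poisson-Gaussian noise,
drift slowly with breathing and tissue relaxation, and — across imaging
sessions days or weeks apart — are rotated and translated relative to each
other. `ivmproc` provides the four processing stages such data needs, as a
library plus a CLI:

- **Denoising** via a variance-stabilizing transform and a collaborative
  (block-matching) Gaussian filter, per 2D image or per chunked 3D volume,
  with a Median-3D baseline.
- **Drift correction** of time series and z-stacks: a feature-rich
  *registration channel* is synthesized by summing all detection channels,
  SIFT keypoints are matched between frames, and a robust per-frame
  translation is applied to every channel.
- **Serial-session registration**: a rigid (rotation + translation)
  transform fitted to 10–20 user-placed landmark pairs (BigWarp-compatible
  CSV), applied by trilinear resampling in physical coordinates.
- **Benchmarking**: ground truth by averaging aligned noisy replicates of
  one volume, and per-slice PSNR/RMSE/MAE reports for any set of denoisers.
- **Synthetic phantoms** emulating the three detection channels of a kidney
  recording (endothelial network, tubular autofluorescence with bright
  puncta, capsule fibrils), so every stage is testable end to end without
  any downloaded data.

## The model at the core

A photon-counting detector observes, per voxel,

```
z = α·p + n,     p ~ Poisson(y),     n ~ N(μ, σ²)
```

with gain `α` (ADU/photon), photon mean `y`, and additive read noise `σ`.
The noise variance `α²y + σ²` depends on the signal, which breaks Gaussian
denoisers. The generalized Anscombe transform (GAT)

```
f(z) = (2/α) · sqrt(α·z + (3/8)·α² + σ² − α·μ)
```

maps the data to approximately unit-variance Gaussian noise. The pipeline
is: estimate `σ` robustly from the data (median absolute deviation of the
finest diagonal wavelet subband, computed on a tiled image of up to 10
evenly spaced slices) → apply the GAT → rescale to [0, 1] → run a two-stage
block-matching collaborative filter (hard thresholding, then empirical
Wiener shrinkage; volumes processed in chunks of 10 frames overlapping by
5) → invert the GAT with either the exact algebraic inverse or the
closed-form approximation of the exact unbiased inverse → quantize back to
the original bit depth.

Landmark registration solves `min_Σ ‖R·mᵢ + t − rᵢ‖²` in closed form
(centroid alignment, SVD of the cross-covariance, determinant-corrected
rotation). Replicate volumes are aligned by true normalized
cross-correlation over the overlap region with sub-voxel quadratic peak
refinement. Image quality is scored as `PSNR = 10·log₁₀(peak²/MSE)` per
slice, with `peak` the reference-slice maximum by default.

## Worked example

Simulate a replicate validation set (one volume imaged 6 times under
Poisson-Gaussian noise with gain 4 ADU/photon and read noise 10 ADU),
then score two denoisers against the clean volume:

```python
from ivmproc import (
    PhantomSpec, PoissonGaussianModel, make_validation_replicates,
    quantize_to_uint, benchmark, denoise_vst, median3d,
)

spec = PhantomSpec(shape=(1, 16, 3, 96, 96), n_filaments=6, n_tubes=2,
                   n_puncta=10, n_fibrils=10, seed=11)
model = PoissonGaussianModel(alpha=4.0, sigma=10.0)
reps, clean, _ = make_validation_replicates(spec, n=6, model=model,
                                            jitter_um=0.0, seed=11)
gt = quantize_to_uint(clean, 16)

methods = {
    "vst3d": lambda s: denoise_vst(s, model=PoissonGaussianModel(alpha=4.0), mode="3d")[0],
    "median3d": lambda s: median3d(s, radius=2),
}
print(benchmark(reps, gt, methods).summary.to_string(index=False))
```

which prints

```
  method     channel  mean_psnr_db  sd_psnr_db  n
     Raw endothelium         27.89        0.34 96
     Raw     tubules         26.80        3.29 96
     Raw     capsule          8.25        5.62 96
   vst3d endothelium         42.23        1.95 96
   vst3d     tubules         38.42        2.80 96
   vst3d     capsule         29.41        1.20 96
median3d endothelium         32.08        2.37 96
median3d     tubules         28.51        1.86 96
median3d     capsule         23.41        1.38 96
```

Read this as: raw PSNR is ordered endothelium > tubules > capsule (the
second-harmonic capsule channel is the weakest signal); both denoisers
improve every channel; the variance-stabilized volumetric filter gains
roughly 14 dB over raw and clearly outperforms the Median-3D baseline,
which trails on the low-SNR capsule channel — the qualitative picture a
replicate benchmark on real kidney data shows.

The same stages are available from the shell:

```
ivmproc simulate --preset validation --out-dir sim --seed 1 --shape 6,16,3,96,96
ivmproc denoise --method vst3d --alpha 4 sim/replicate_000.ome.tif den.ome.tif
ivmproc drift-correct --axis t tseries.ome.tif aligned.ome.tif --shifts-out shifts.csv
ivmproc register3d --landmarks lm.csv --reference day1.ome.tif day7.ome.tif out.ome.tif
ivmproc benchmark --methods vst2d,vst3d,median3d --gt gt.ome.tif \
    --replicates 'sim/replicate_*.ome.tif' --out report.csv
ivmproc run pipeline.yaml       # config-driven multi-stage batch run
```

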