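"""Variance-stabilized denoising of Poisson-Gaussian microscopy data.

Photon-counting detectors produce mixed Poisson-Gaussian noise: an observed
intensity is ``z = alpha * p + n`` with ``p ~ Poisson(y)`` photons, detector
gain ``alpha`` (ADU/photon) and additive read-out noise ``n ~ N(mu, sigma^2)``.
Gaussian patch denoisers assume signal-independent noise, so the pipeline
follows the classic four steps:

1. estimate the residual Gaussian noise level on the data itself,
2. apply the generalized Anscombe transform (GAT) so the noise becomes
   approximately unit-variance Gaussian,
3. run a collaborative (block-matching) Gaussian filter on the stabilized,
   [0, 1]-rescaled data — per 2D image, or per overlapping chunk of frames
   for volumes,
4. invert the GAT (algebraic, or the closed-form approximation of the exact
   unbiased inverse) and quantize back to the original bit depth.

A Median-3D filter is included as the conventional baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import ndimage

from . import core_io
from ._blockmatch import BlockMatchParams, block_match_filter
from .core_io import Stack5D

logger = logging.getLogger("ivmproc")

__all__ = [
    "PoissonGaussianModel",
    "VSTConfig",
    "RescaleRecord",
    "estimate_noise_sigma",
    "build_estimation_tile",
    "gat_forward",
    "gat_inverse",
    "rescale_unit",
    "unrescale_unit",
    "median3d",
    "chunk_plan",
    "collaborative_filter",
    "denoise_vst",
]


@dataclass(frozen=True)
class PoissonGaussianModel:
    """Detector noise model ``z = alpha * Poisson(y) + N(mu, sigma^2)``.

    ``alpha`` is the gain in ADU/photon, ``sigma`` the additive Gaussian
    standard deviation in ADU and ``mu`` the detector offset in ADU.
    """

    alpha: float = 1.0
    sigma: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"gain alpha must be > 0, got {self.alpha}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class VSTConfig:
    """Parameters of the variance-stabilized denoising pipeline.

    Volumes are split into chunks of ``chunk_length`` frames overlapping by
    ``chunk_overlap`` frames at each extremity; the noise level is estimated
    on a tiled image built from up to ``tile_max_slices`` evenly spaced
    slices.  The collaborative-filter knobs (hard threshold multiplier,
    search window, group size) are defaults, not hard-coded constants.
    """

    chunk_length: int = 10
    chunk_overlap: int = 5
    tile_max_slices: int = 10
    inverse_mode: str = "exact_unbiased"  # or "algebraic"
    filter_backend: str = "internal"  # or "identity" (diagnostic pass-through)
    hard_threshold: float = 2.7
    search_window: int = 39
    group_size: int = 16
    patch_size_2d: int = 8
    patch_size_3d: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.chunk_overlap < self.chunk_length:
            raise ValueError("require 0 <= chunk_overlap < chunk_length")
        if self.tile_max_slices < 1:
            raise ValueError("tile_max_slices must be >= 1")
        if self.inverse_mode not in ("algebraic", "exact_unbiased"):
            raise ValueError(f"unknown inverse_mode {self.inverse_mode!r}")
        if self.filter_backend not in ("internal", "identity"):
            raise ValueError(f"unknown filter_backend {self.filter_backend!r}")


# ---------------------------------------------------------------------------
# noise level estimation
# ---------------------------------------------------------------------------

def estimate_noise_sigma(image: np.ndarray) -> float:
    """Estimate the additive Gaussian noise std of a 2D image, in ADU.

    Uses the median absolute deviation of the finest diagonal wavelet detail
    coefficients (db2), which is robust to image structure: edges contribute
    only sparsely to the diagonal subband so the median ignores them.  A
    constant image returns 0 with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 16:
        raise ValueError("estimate_noise_sigma expects a 2D image of at least 16x16")
    if np.ptp(image) == 0:
        logger.warning("estimate_noise_sigma: constant image, nothing to estimate")
        return 0.0
    _, (_, _, diag) = pywt.dwt2(image, "db2")
    # 0.6745 = Phi^-1(0.75): MAD -> std for Gaussian noise
    return float(np.median(np.abs(diag)) / 0.6745)


def build_estimation_tile(stack: Stack5D, max_slices: int = 10, channel: int = 0) -> np.ndarray:
    """Mosaic of up to ``max_slices`` evenly spaced slices for noise estimation.

    ``k = min(max_slices, n_slices)`` slice indices are chosen as
    ``round(linspace(0, n - 1, k))`` and arranged row-major in a
    ``ceil(sqrt(k))``-column grid; missing cells of the last row are
    zero-padded.  Tiling pools more pixels than a single slice and makes the
    MAD estimate less sensitive to one unrepresentative plane.
    """
    frames = stack.data[:, :, channel].reshape(-1, stack.shape[3], stack.shape[4])
    n = frames.shape[0]
    k = min(int(max_slices), n)
    idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
    k = len(idx)
    if k == 1:
        return np.asarray(frames[idx[0]], dtype=np.float64)
    cols = int(np.ceil(np.sqrt(k)))
    rows = int(np.ceil(k / cols))
    h, w = frames.shape[1], frames.shape[2]
    tile = np.zeros((rows * h, cols * w), dtype=np.float64)
    for i, s in enumerate(idx):
        r, c = divmod(i, cols)
        tile[r * h : (r + 1) * h, c * w : (c + 1) * w] = frames[s]
    return tile


def estimation_slice_indices(n_slices: int, max_slices: int = 10) -> np.ndarray:
    """Indices of the slices that enter the estimation tile."""
    k = min(int(max_slices), int(n_slices))
    return np.unique(np.round(np.linspace(0, n_slices - 1, k)).astype(int))


# ---------------------------------------------------------------------------
# generalized Anscombe transform
# ---------------------------------------------------------------------------

def gat_forward(image: np.ndarray, model: PoissonGaussianModel) -> np.ndarray:
    """Generalized Anscombe transform: stabilize Poisson-Gaussian noise to var 1.

    ``f(z) = (2/alpha) * sqrt(alpha*z + (3/8)*alpha^2 + sigma^2 - alpha*mu)``
    where the radicand is positive, else 0.  In the moderate/high count
    regime the transformed noise variance is approximately 1.
    """
    z = np.asarray(image, dtype=np.float64)
    a, s, m = model.alpha, model.sigma, model.mu
    radicand = a * z + 0.375 * a * a + s * s - a * m
    return np.where(radicand > 0, (2.0 / a) * np.sqrt(np.maximum(radicand, 0.0)), 0.0)


def gat_inverse(image: np.ndarray, model: PoissonGaussianModel, mode: str = "algebraic") -> np.ndarray:
    """Map stabilized values back to intensities in ADU.

    ``algebraic`` exactly inverts :func:`gat_forward` on its range.
    ``exact_unbiased`` applies the closed-form approximation of the exact
    unbiased inverse of the unit-gain Anscombe transform,

        I(D) = D^2/4 + sqrt(3/2)/4 D^-1 - 11/8 D^-2 + 5/8 sqrt(3/2) D^-3 - 1/8,

    generalized to (alpha, sigma, mu) by the variable substitution
    ``z' = (z - mu)/alpha``, ``sigma' = sigma/alpha`` (subtracting
    ``sigma'^2`` inside and rescaling by ``alpha`` outside).  The unbiased
    inverse is designed to act on a *denoised* stabilized value, i.e. an
    estimate of ``E[f(z)]``; applied there it removes the small-count bias
    of the algebraic inverse.  Negative outputs are clipped to 0.
    """
    D = np.asarray(image, dtype=np.float64)
    a, s, m = model.alpha, model.sigma, model.mu
    sp2 = (s / a) ** 2
    if mode == "algebraic":
        y = (D / 2.0) ** 2 - 0.375 - sp2  # photon units
    elif mode == "exact_unbiased":
        # gat_forward already yields the unit-gain stabilized value
        # D = 2*sqrt(z' + 3/8 + sigma'^2) with z' = (z - mu)/alpha
        Da = D
        with np.errstate(divide="ignore", invalid="ignore"):
            y = (
                Da**2 / 4.0
                + np.sqrt(1.5) / 4.0 / Da
                - 11.0 / 8.0 / Da**2
                + 5.0 / 8.0 * np.sqrt(1.5) / Da**3
                - 1.0 / 8.0
                - sp2
            )
        y = np.where(Da > 0, y, -np.inf)
    else:
        raise ValueError(f"unknown inverse mode {mode!r}")
    out = a * y + m
    n_neg = int(np.count_nonzero(out < 0))
    if n_neg:
        logger.debug("gat_inverse clipped %d negative intensities to 0", n_neg)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# [0, 1] rescale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RescaleRecord:
    """Linear map applied by :func:`rescale_unit`, needed to undo it exactly."""

    offset: float
    scale: float  # multiplicative factor applied to (x - offset); 1/(max-min)
    degenerate: bool = False


def rescale_unit(image: np.ndarray) -> tuple[np.ndarray, RescaleRecord]:
    """Linearly map [min, max] to [0, 1]; constant input maps to 0 (degenerate)."""
    x = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("rescale_unit requires finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x), RescaleRecord(offset=lo, scale=1.0, degenerate=True)
    scale = 1.0 / (hi - lo)
    return (x - lo) * scale, RescaleRecord(offset=lo, scale=scale)


def unrescale_unit(image: np.ndarray, record: RescaleRecord) -> np.ndarray:
    """Exact inverse of :func:`rescale_unit`."""
    x = np.asarray(image, dtype=np.float64)
    if record.degenerate:
        return np.full_like(x, record.offset)
    return x / record.scale + record.offset


# ---------------------------------------------------------------------------
# Median 3D baseline
# ---------------------------------------------------------------------------

def median3d(stack: Stack5D, radius: int = 2) -> Stack5D:
    """Median filter over the ``(2r+1)^3`` z/y/x neighborhood, per (t, c).

    The conventional FIJI baseline with a radius of 2 voxels per axis.
    Borders use neighborhood truncation: the median is taken over in-bounds
    voxels only, not over padded values.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    size = 2 * r + 1
    out = np.empty_like(stack.data)
    for t in range(stack.n_t):
        for c in range(stack.n_c):
            vol = np.asarray(stack.data[t, :, c], dtype=np.float64)
            filt = ndimage.median_filter(vol, size=size, mode="reflect")
            _fix_truncated_borders(vol, filt, r)
            if stack.is_float:
                out[t, :, c] = filt
            else:
                # truncated even-count windows can yield half-integer medians;
                # round half away from zero, matching the quantization convention
                out[t, :, c] = np.clip(np.floor(filt + 0.5), 0, 2**stack.bit_depth - 1)
    return stack.with_data(out)


def _fix_truncated_borders(vol: np.ndarray, filt: np.ndarray, r: int) -> None:
    """Replace the border shell of ``filt`` with truncated-window medians."""
    size = 2 * r + 1
    padded = np.pad(vol, r, mode="constant", constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (size, size, size))
    shell = np.zeros(vol.shape, dtype=bool)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, min(r, vol.shape[ax]))
        sl_hi[ax] = slice(max(vol.shape[ax] - r, 0), vol.shape[ax])
        shell[tuple(sl_lo)] = True
        shell[tuple(sl_hi)] = True
    idx = np.nonzero(shell)
    if idx[0].size:
        filt[idx] = np.nanmedian(windows[idx].reshape(idx[0].size, -1), axis=1)


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

def chunk_plan(n_frames: int, length: int = 10, overlap: int = 5) -> list[tuple[int, int, int, int]]:
    """Overlapping chunk layout along the frame axis.

    Returns ``(start, stop, keep_start, keep_stop)`` tuples.  Consecutive
    chunks advance by ``length - overlap``; the last chunk is clipped to
    ``n_frames``.  Each frame is *owned* by exactly one chunk — the one whose
    center is nearest (ties to the earlier chunk) — so the keep-ranges
    partition ``[0, n_frames)`` and chunk merging needs no blending.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= overlap < length:
        raise ValueError("require 0 <= overlap < length")
    stride = length - overlap
    starts = [0]
    while starts[-1] + length < n_frames:
        starts.append(starts[-1] + stride)
    bounds = [(s, min(s + length, n_frames)) for s in starts]
    centers = np.array([(a + b - 1) / 2.0 for a, b in bounds])
    frames = np.arange(n_frames)
    dist = np.abs(frames[:, None] - centers[None, :])
    # a frame can only be owned by a chunk that contains it
    for i, (a, b) in enumerate(bounds):
        dist[(frames < a) | (frames >= b), i] = np.inf
    owner = np.argmin(dist, axis=1)
    plan = []
    for i, (a, b) in enumerate(bounds):
        owned = np.nonzero(owner == i)[0]
        keep_start, keep_stop = int(owned[0]), int(owned[-1]) + 1
        plan.append((a, b, keep_start, keep_stop))
    return plan


# ---------------------------------------------------------------------------
# collaborative filter
# ---------------------------------------------------------------------------

def _bm_params(ndim: int, config: VSTConfig) -> BlockMatchParams:
    radius = (config.search_window - 1) // 2
    if ndim == 2:
        return BlockMatchParams(
            patch=(config.patch_size_2d,) * 2,
            ref_step=(4, 4),
            search_radius=(radius, radius),
            cand_step=(2, 2),
            group_size=config.group_size,
            hard_threshold=config.hard_threshold,
        )
    return BlockMatchParams(
        patch=(config.patch_size_3d,) * 3,
        ref_step=(2, 4, 4),
        search_radius=(min(radius, 2), min(radius, 8), min(radius, 8)),
        cand_step=(1, 2, 2),
        group_size=config.group_size,
        hard_threshold=config.hard_threshold,
    )


def collaborative_filter(
    data: np.ndarray, noise_std: float = 1.0, config: VSTConfig | None = None
) -> np.ndarray:
    """Two-stage patch-grouping collaborative Gaussian denoiser (2D or 3D).

    Stage 1 groups mutually similar patches (8x8 in 2D, 4x4x4 cubes in 3D)
    found by block matching within a bounded search window, applies a
    separable orthogonal DCT across the group, hard-thresholds coefficients
    at ``hard_threshold * noise_std`` and aggregates overlapping estimates by
    weighted averaging.  Stage 2 repeats the grouping on the first estimate
    and shrinks coefficients with an empirical Wiener filter.  Deterministic.

    ``data`` is expected in the [0, 1]-rescaled stabilized domain (a warning
    is logged outside it); ``noise_std`` is the noise level on that scale.
    """
    config = config or VSTConfig()
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError("collaborative_filter expects a 2D image or 3D volume")
    if arr.min() < -0.05 or arr.max() > 1.05:
        logger.warning(
            "collaborative_filter input outside [0, 1] (range [%.3g, %.3g])", arr.min(), arr.max()
        )
    if noise_std <= 0:
        return arr.copy()
    return block_match_filter(arr, float(noise_std), _bm_params(arr.ndim, config))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _filter_channel_2d(frames: np.ndarray, noise_std: float, config: VSTConfig) -> np.ndarray:
    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        out[i] = collaborative_filter(frames[i], noise_std, config)
    return out


def _filter_channel_3d(frames: np.ndarray, noise_std: float, config: VSTConfig) -> np.ndarray:
    n = frames.shape[0]
    out = np.empty_like(frames)
    for start, stop, keep_a, keep_b in chunk_plan(n, config.chunk_length, config.chunk_overlap):
        filt = collaborative_filter(frames[start:stop], noise_std, config)
        out[keep_a:keep_b] = filt[keep_a - start : keep_b - start]
    return out


def denoise_vst(
    stack: Stack5D,
    config: VSTConfig | None = None,
    model: PoissonGaussianModel | None = None,
    mode: str = "3d",
) -> tuple[Stack5D, dict]:
    """Run the full variance-stabilized denoising pipeline on an integer stack.

    Per channel: the noise std is estimated once — on the middle slice in 2D
    mode, on the tiled estimation image in 3D mode; the GAT is applied with
    that sigma (gain/offset from ``model``, defaulting to alpha=1, mu=0);
    intensities are rescaled to [0, 1]; the collaborative filter runs per 2D
    frame or per overlapping frame chunk; the result is mapped back through
    the rescale, the inverse GAT and quantization to the original bit depth.

    Frames are z-slices when the stack has a z extent > 1, else time points.
    Returns the denoised stack and a report with the per-channel sigma
    estimates.
    """
    config = config or VSTConfig()
    if stack.is_float:
        raise ValueError("denoise_vst expects an integer input stack")
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    base = model or PoissonGaussianModel()

    nt, nz, nc, ny, nx = stack.shape
    frame_axis_is_z = nz > 1
    out = np.empty(stack.shape, dtype=np.float64)
    sigmas: dict[str, float] = {}
    for c in range(nc):
        chan = np.asarray(stack.data[:, :, c], dtype=np.float64)  # (t, z, y, x)
        if mode == "2d":
            est_img = chan.reshape(-1, ny, nx)[chan.shape[0] * chan.shape[1] // 2]
        else:
            est_img = build_estimation_tile(stack, config.tile_max_slices, channel=c)
        sigma = estimate_noise_sigma(est_img)
        sigmas[stack.channel_names[c]] = sigma
        m = PoissonGaussianModel(alpha=base.alpha, sigma=sigma, mu=base.mu)

        stabilized = gat_forward(chan, m)
        scaled, record = rescale_unit(stabilized)
        noise_std = 1.0 * record.scale  # unit-variance noise after GAT, squeezed by rescale

        if config.filter_backend == "identity":
            filtered = scaled
        else:
            if frame_axis_is_z:
                filtered = np.empty_like(scaled)
                for t in range(nt):
                    if mode == "2d":
                        filtered[t] = _filter_channel_2d(scaled[t], noise_std, config)
                    else:
                        filtered[t] = _filter_channel_3d(scaled[t], noise_std, config)
            else:
                series = scaled[:, 0]  # (t, y, x): frames are time points
                if mode == "2d":
                    flt = _filter_channel_2d(series, noise_std, config)
                else:
                    flt = _filter_channel_3d(series, noise_std, config)
                filtered = flt[:, None]

        restored = unrescale_unit(filtered, record)
        out[:, :, c] = gat_inverse(restored, m, config.inverse_mode)

    float_stack = stack.with_data(out.astype(np.float32), bit_depth=32, is_float=True)
    result = core_io.quantize_to_uint(float_stack, stack.bit_depth)
    report = {"mode": mode, "inverse_mode": config.inverse_mode, "sigma_per_channel": sigmas}
    logger.info("denoise_vst(%s): sigma estimates %s", mode, sigmas)
    return result, report
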