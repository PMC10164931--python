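"""Sample-drift correction of time series and z-stacks.

Breathing and tissue relaxation cause slow lateral drifts during live
imaging.  Correction is feature-based and translation-only: a synthetic
*registration channel* is built by summing all detection channels (single
channels are often too sparse in features), each frame is contrast-
stretched, multi-scale SIFT keypoints are matched between frames, and a
robust translation is fitted per frame pair.  The estimated shifts are then
applied to every original channel and the registration channel is
discarded.  A pair that cannot be matched reliably falls back to a zero
shift and is flagged — a batch run never aborts on one bad frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors
from skimage.transform import resize

from .core_io import Stack5D

logger = logging.getLogger("ivmproc")

__all__ = [
    "SIFTParams",
    "TranslationSeries",
    "enhance_contrast_frame",
    "build_registration_channel",
    "estimate_translations",
    "apply_translations",
    "register_2d",
]


@dataclass
class SIFTParams:
    """Feature detection and matching parameters for translation estimation.

    Defaults mirror the common stack-alignment convention: initial blur 1.5
    px, 3 steps per scale octave, octaves bounded so the coarsest image is
    not smaller than ``min_image_size`` px and estimation happens at most at
    ``max_image_size`` px (larger frames are downscaled first), descriptor
    grids of ``descriptor_size`` spatial bins, a nearest-neighbor ratio test
    and a translation-only consensus fit with outlier rejection.
    """

    initial_blur: float = 1.5
    steps_per_octave: int = 3
    min_image_size: int = 64
    max_image_size: int = 512
    descriptor_size: int = 8
    transform_model: str = "translation"
    match_ratio: float = 0.92
    min_inliers: int = 7
    inlier_epsilon: float = 3.0

    def __post_init__(self) -> None:
        if self.min_image_size >= self.max_image_size:
            raise ValueError("min_image_size must be < max_image_size")
        if self.steps_per_octave < 1:
            raise ValueError("steps_per_octave must be >= 1")
        if self.transform_model != "translation":
            raise ValueError("only the translation model is supported")


@dataclass
class TranslationSeries:
    """Per-frame correction shifts (dx, dy) mapping each frame into reference coords."""

    shifts: np.ndarray  # (n, 2) as (dx, dy)
    reference_index: int = 0
    n_inliers: np.ndarray | None = None
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n, 2)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")
        n = self.shifts.shape[0]
        if self.n_inliers is None:
            self.n_inliers = np.zeros(n, dtype=int)
        if self.flagged is None:
            self.flagged = np.zeros(n, dtype=bool)
        if not np.allclose(self.shifts[self.reference_index], 0.0):
            raise ValueError("the reference frame must have zero shift")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    def negate(self) -> "TranslationSeries":
        return TranslationSeries(
            -self.shifts, self.reference_index, self.n_inliers.copy(), self.flagged.copy()
        )


def enhance_contrast_frame(
    frame: np.ndarray, saturated_fraction: float = 0.01, normalize: bool = True, target_max: float = 1.0
) -> np.ndarray:
    """Per-frame histogram stretch with tail saturation.

    Clips ``saturated_fraction/2`` of the pixels at each histogram tail and
    maps the remaining range linearly onto ``[0, target_max]``.  A constant
    frame passes through unchanged.
    """
    f = np.asarray(frame, dtype=np.float64)
    lo = np.quantile(f, saturated_fraction / 2.0)
    hi = np.quantile(f, 1.0 - saturated_fraction / 2.0)
    if hi <= lo:
        return f.copy()
    out = np.clip((f - lo) / (hi - lo), 0.0, 1.0)
    return out * target_max if normalize else out * (hi - lo) + lo


def build_registration_channel(stack: Stack5D, saturated_fraction: float = 0.01) -> Stack5D:
    """Single-channel stack: channel sum, per-frame contrast stretch, requantized.

    The raw values of all channels are added in floating point (addition
    commutes, so the result is channel-order invariant), each (t, z) frame
    is contrast-enhanced over the full target range, and the result is
    rescaled to the input bit depth.
    """
    total = np.asarray(stack.data, dtype=np.float64).sum(axis=2, keepdims=True)
    hi = 1.0 if stack.is_float else float(2**stack.bit_depth - 1)
    out = np.empty_like(total)
    for t in range(stack.n_t):
        for z in range(stack.n_z):
            out[t, z, 0] = enhance_contrast_frame(
                total[t, z, 0], saturated_fraction, normalize=True, target_max=hi
            )
    if stack.is_float:
        data = out.astype(np.float32)
    else:
        data = np.clip(np.floor(out + 0.5), 0, int(hi)).astype(stack.data.dtype)
    return stack.with_data(data, channel_names=["registration"])


def _detect(frame: np.ndarray, params: SIFTParams):
    h, w = frame.shape
    n_octaves = max(1, int(np.floor(np.log2(min(h, w) / params.min_image_size))) + 1)
    det = SIFT(
        n_octaves=n_octaves,
        n_scales=params.steps_per_octave,
        sigma_min=params.initial_blur,
    )
    det.detect_and_extract(frame)
    return det.keypoints.astype(np.float64), det.descriptors


def _pair_shift(ka, da, kb, db, params: SIFTParams) -> tuple[np.ndarray, int, bool]:
    """Displacement (drow, dcol) of frame b's content relative to frame a."""
    if da is None or db is None or len(da) < 2 or len(db) < 2:
        return np.zeros(2), 0, True
    matches = match_descriptors(da, db, max_ratio=params.match_ratio, cross_check=True)
    if matches.shape[0] < params.min_inliers:
        return np.zeros(2), int(matches.shape[0]), True
    disp = kb[matches[:, 1]] - ka[matches[:, 0]]
    # translation-only consensus: every match proposes a candidate shift;
    # the candidate with the most inliers within epsilon wins, then the
    # inlier displacements are averaged (sub-pixel)
    best_inliers = None
    for cand in disp:
        inl = np.linalg.norm(disp - cand, axis=1) < params.inlier_epsilon
        if best_inliers is None or inl.sum() > best_inliers.sum():
            best_inliers = inl
    n_inl = int(best_inliers.sum())
    if n_inl < params.min_inliers:
        return np.zeros(2), n_inl, True
    return disp[best_inliers].mean(axis=0), n_inl, False


def estimate_translations(
    frames: np.ndarray, params: SIFTParams | None = None, mode: str = "sequential"
) -> TranslationSeries:
    """Estimate per-frame correction shifts for a (n, y, x) frame series.

    ``sequential`` estimates each consecutive pair and composes the pairwise
    shifts into shifts-to-reference (frame 0); ``fixed-ref`` matches every
    frame directly against frame 0 (useful for slow drifts in time series).
    Frames larger than ``max_image_size`` are downscaled for estimation and
    the shifts are scaled back.
    """
    params = params or SIFTParams()
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("estimate_translations expects (n>=2, y, x) frames")
    if min(frames.shape[1:]) < params.min_image_size:
        raise ValueError(f"frame size {frames.shape[1:]} below min_image_size {params.min_image_size}")
    if mode not in ("sequential", "fixed-ref"):
        raise ValueError(f"unknown mode {mode!r}")

    factor = 1.0
    h, w = frames.shape[1:]
    if max(h, w) > params.max_image_size:
        factor = params.max_image_size / max(h, w)
        small = np.stack(
            [
                resize(f, (round(h * factor), round(w * factor)), anti_aliasing=True, preserve_range=True)
                for f in frames
            ]
        )
    else:
        small = frames

    feats = []
    for f in small:
        try:
            feats.append(_detect(f, params))
        except (RuntimeError, ValueError):
            feats.append((None, None))

    n = frames.shape[0]
    cum = np.zeros((n, 2))  # cumulative content displacement (drow, dcol) vs frame 0
    inliers = np.zeros(n, dtype=int)
    flagged = np.zeros(n, dtype=bool)
    for i in range(1, n):
        a = i - 1 if mode == "sequential" else 0
        ka, da = feats[a]
        kb, db = feats[i]
        d, n_inl, bad = _pair_shift(ka, da, kb, db, params)
        inliers[i] = n_inl
        flagged[i] = bad
        cum[i] = (cum[i - 1] + d) if mode == "sequential" else d
        if bad:
            logger.warning("frame %d: only %d inlier matches; falling back to zero shift", i, n_inl)
    cum /= factor
    # correction maps each frame back into frame-0 coordinates
    shifts = np.stack([-cum[:, 1], -cum[:, 0]], axis=1)  # (dx, dy)
    return TranslationSeries(shifts, reference_index=0, n_inliers=inliers, flagged=flagged)


def apply_translations(stack: Stack5D, series: TranslationSeries, axis: str = "t") -> Stack5D:
    """Translate every channel of frame i by ``series.shifts[i]`` (bilinear, zero fill)."""
    if axis not in ("t", "z"):
        raise ValueError("axis must be 't' or 'z'")
    n = stack.n_t if axis == "t" else stack.n_z
    if len(series) != n:
        raise ValueError(f"series has {len(series)} shifts for {n} frames along {axis}")
    out = np.array(stack.data, dtype=np.float64)
    for i, (dx, dy) in enumerate(series.shifts):
        if dx == 0 and dy == 0:
            continue
        sel = (i, slice(None)) if axis == "t" else (slice(None), i)
        out[sel] = ndimage.shift(out[sel], (0, 0, dy, dx), order=1, mode="constant", cval=0.0)
    if stack.is_float:
        data = out.astype(np.float32)
    else:
        data = np.clip(np.floor(out + 0.5), 0, 2**stack.bit_depth - 1).astype(stack.data.dtype)
    return stack.with_data(data)


def register_2d(
    stack: Stack5D, params: SIFTParams | None = None, axis: str = "t", mode: str = "sequential"
) -> tuple[Stack5D, TranslationSeries]:
    """Drift-correct a Tseries (axis 't') or Zstack (axis 'z').

    Builds the registration channel, estimates per-frame translations on it,
    applies them to all original channels and discards the registration
    channel.  Returns the aligned stack and the shift series report.
    """
    if axis == "t" and stack.n_z != 1:
        raise ValueError("axis 't' expects a time series with a single z plane")
    if axis == "z" and stack.n_t != 1:
        raise ValueError("axis 'z' expects a single-timepoint volume")
    reg = build_registration_channel(stack)
    frames = np.asarray(reg.data, dtype=np.float64).reshape(-1, stack.shape[3], stack.shape[4])
    series = estimate_translations(frames, params, mode=mode)
    aligned = apply_translations(stack, series, axis=axis)
    return aligned, series
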