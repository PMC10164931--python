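"""Two-stage block-matching collaborative filter (dimension-agnostic core).

A patch-grouping transform-shrinkage denoiser for Gaussian noise in the
style of the classic collaborative filtering family: mutually similar
patches are stacked into a group, a separable orthogonal DCT is applied
over the patch axes and across the group, coefficients are shrunk (hard
thresholding in stage 1, empirical Wiener in stage 2) and the filtered
patches are aggregated back by weighted averaging.  The implementation is
vectorized over candidate offsets: for every offset the patchwise squared
distance field is obtained from a box sum of the shifted squared
difference image, so matching costs one pass over the data per offset.

Everything is deterministic; there is no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage


@dataclass(frozen=True)
class BlockMatchParams:
    patch: tuple[int, ...]
    ref_step: tuple[int, ...]
    search_radius: tuple[int, ...]
    cand_step: tuple[int, ...]
    group_size: int = 16
    hard_threshold: float = 2.7


def _axis_positions(extent: int, patch: int, step: int) -> np.ndarray:
    """Reference-patch start positions covering [0, extent - patch]."""
    last = extent - patch
    if last < 0:
        raise ValueError(f"image extent {extent} smaller than patch {patch}")
    pos = np.arange(0, last + 1, step)
    if pos[-1] != last:
        pos = np.append(pos, last)
    return pos


def _offsets(params: BlockMatchParams, shape: tuple[int, ...]) -> np.ndarray:
    ranges = []
    for r, s, n, p in zip(params.search_radius, params.cand_step, shape, params.patch):
        r = min(r, n - p)  # larger offsets can never land a candidate in bounds
        vals = np.arange(-r, r + 1, s)
        if 0 not in vals:
            vals = np.sort(np.append(vals, 0))
        ranges.append(vals)
    return np.array(list(product(*ranges)), dtype=np.int64)


def _box_sum(a: np.ndarray, patch: tuple[int, ...]) -> np.ndarray:
    """Sum of ``a`` over every window of shape ``patch`` (valid positions only)."""
    mean = ndimage.uniform_filter(np.asarray(a, dtype=np.float64), size=patch, mode="constant")
    # centered output at index pos + p//2 equals the mean of the window
    # starting at pos; slice the positions whose window is fully in bounds
    sl = tuple(slice(p // 2, n - p + 1 + p // 2) for p, n in zip(patch, a.shape))
    return mean[sl] * float(np.prod(patch))


def _match(
    img: np.ndarray, params: BlockMatchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Find, for each reference patch, the group of most similar patch positions.

    Returns ``(ref_grid, members)`` where ``members`` has shape
    ``(n_ref, group_size, ndim)`` holding patch start coordinates.
    """
    ndim = img.ndim
    patch = params.patch
    pos_axes = [_axis_positions(img.shape[i], patch[i], params.ref_step[i]) for i in range(ndim)]
    grids = np.meshgrid(*pos_axes, indexing="ij")
    refs = np.stack([g.ravel() for g in grids], axis=-1)  # (n_ref, ndim)
    n_ref = refs.shape[0]
    offsets = _offsets(params, img.shape)
    n_off = offsets.shape[0]
    max_start = np.array(img.shape) - np.array(patch)  # inclusive

    # validity of candidate positions, for all offsets at once
    cand = refs[None, :, :] + offsets[:, None, :]
    valid = np.all((cand >= 0) & (cand <= max_start[None, None, :]), axis=2)  # (n_off, n_ref)

    dist = np.full((n_off, n_ref), np.inf, dtype=np.float64)
    for k in range(n_off):
        off = offsets[k]
        if not np.any(off):
            dist[k] = 0.0
            continue
        src = tuple(slice(max(0, -o), img.shape[i] - max(0, o)) for i, o in enumerate(off))
        dst = tuple(slice(max(0, o), img.shape[i] - max(0, -o)) for i, o in enumerate(off))
        d2 = np.square(img[dst] - img[src])
        # d2 position q corresponds to reference start q + max(0, -o) per axis;
        # candidate validity coincides with box-index validity
        box = _box_sum(d2, patch)
        sel = valid[k]
        rel = refs[sel] + np.minimum(off, 0)
        dist[k, sel] = box[tuple(rel.T)]

    g = min(params.group_size, n_off)
    top = np.argpartition(dist, g - 1, axis=0)[:g]  # (g, n_ref)
    members = refs[None, :, :] + offsets[top]  # (g, n_ref, ndim)
    # invalid candidates carry inf distance and are never selected unless fewer
    # than g valid offsets exist; clamp as a belt-and-braces guard
    members = np.clip(members.transpose(1, 0, 2), 0, max_start)  # (n_ref, g, ndim)
    return refs, members


def _group_dct(groups: np.ndarray, ndim: int, inverse: bool = False) -> np.ndarray:
    """Orthonormal DCT over the group axis (1) and the patch axes (2..)."""
    fn = sp_fft.idctn if inverse else sp_fft.dctn
    axes = tuple(range(1, 2 + ndim))
    return fn(groups, axes=axes, norm="ortho", type=2)


def _gather(img: np.ndarray, members: np.ndarray, patch: tuple[int, ...]) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(img, patch)
    return windows[tuple(members[..., i] for i in range(img.ndim))]


def _aggregate(
    shape: tuple[int, ...],
    members: np.ndarray,
    patches: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Weighted overlap-add of per-group patch estimates."""
    ndim = len(shape)
    patch = patches.shape[2:]
    n_ref, g = members.shape[:2]
    # flat index of every voxel of every patch
    idx = np.zeros((n_ref, g) + patch, dtype=np.int64)
    stride = np.cumprod((1,) + shape[::-1][:-1])[::-1]
    for ax in range(ndim):
        offs = np.arange(patch[ax]).reshape((1, 1) + tuple(patch[ax] if i == ax else 1 for i in range(ndim)))
        coord = members[..., ax].reshape(n_ref, g, *([1] * ndim)) + offs
        idx += coord * stride[ax]
    w = weights.reshape(n_ref, 1, *([1] * ndim))
    num = np.bincount(idx.ravel(), weights=(patches * w).ravel(), minlength=int(np.prod(shape)))
    den = np.bincount(idx.ravel(), weights=np.broadcast_to(w, patches.shape).ravel(), minlength=int(np.prod(shape)))
    den[den == 0] = 1.0
    return (num / den).reshape(shape)


def block_match_filter(img: np.ndarray, noise_std: float, params: BlockMatchParams) -> np.ndarray:
    """Run both stages (hard threshold, then empirical Wiener) and return the estimate."""
    img = np.asarray(img, dtype=np.float64)
    ndim = img.ndim
    patch = params.patch
    if any(img.shape[i] < patch[i] for i in range(ndim)):
        return img.copy()  # smaller than one patch: nothing to group

    # ---- stage 1: hard thresholding, matched on the noisy data ----
    refs, members = _match(img, params)
    groups = _gather(img, members, patch)
    coef = _group_dct(groups, ndim)
    thr = params.hard_threshold * noise_std
    kept = np.abs(coef) >= thr
    coef = np.where(kept, coef, 0.0)
    n_kept = kept.reshape(kept.shape[0], -1).sum(axis=1)
    weights = 1.0 / np.maximum(n_kept, 1)
    basic = _aggregate(img.shape, members, _group_dct(coef, ndim, inverse=True), weights)

    # ---- stage 2: empirical Wiener shrinkage, matched on the basic estimate ----
    refs2, members2 = _match(basic, params)
    g_noisy = _gather(img, members2, patch)
    g_basic = _gather(basic, members2, patch)
    cb = _group_dct(g_basic, ndim)
    wien = cb**2 / (cb**2 + noise_std**2)
    est = _group_dct(wien * _group_dct(g_noisy, ndim), ndim, inverse=True)
    w2 = 1.0 / np.maximum((wien**2).reshape(wien.shape[0], -1).sum(axis=1), 1e-12)
    return _aggregate(img.shape, members2, est, w2)
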