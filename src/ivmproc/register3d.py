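"""Landmark-based rigid 3D registration of serial imaging sessions.

Serial intravital sessions of the same tissue differ by a rigid motion
(plus possible tissue shrinkage, which rigid registration deliberately does
not model: non-rigid warps can hide true changes in structure size or
shape).  A user places 10-20 corresponding landmarks on tissue features in
the reference and moving volumes; the least-squares rigid transform is the
classic closed-form solution (centroid alignment, SVD of the cross-
covariance, determinant-corrected rotation).  Volumes are resampled by
pulling through the inverse transform with trilinear interpolation in
physical coordinates, so anisotropic voxels are handled naturally.

Also provides translation-only alignment of replicate volumes by
cross-correlation, used when building a ground truth by averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import Stack5D

logger = logging.getLogger("ivmproc")

__all__ = [
    "LandmarkSet",
    "RigidTransform3D",
    "fit_rigid",
    "landmark_residuals",
    "resample_volume",
    "register_serial",
    "align_replicates_translation",
]


class DegenerateLandmarksError(ValueError):
    """Fewer than 3 active pairs, or (near-)collinear active moving points."""


@dataclass
class LandmarkSet:
    """Paired landmark coordinates in physical µm, (x, y, z) per point.

    The CSV dialect is compatible with BigWarp's export: headerless rows of
    ``name, active, moving x, y, z, fixed x, y, z``.
    """

    moving: np.ndarray  # (n, 3)
    reference: np.ndarray  # (n, 3)
    names: list[str] = field(default_factory=list)
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=np.float64))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=np.float64))
        if self.moving.shape != self.reference.shape or self.moving.shape[1] != 3:
            raise ValueError("moving and reference must both be (n, 3) point arrays")
        n = self.moving.shape[0]
        if not self.names:
            self.names = [f"Pt-{i}" for i in range(n)]
        if self.active is None:
            self.active = np.ones(n, dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)
        if len(self.names) != n or self.active.shape != (n,):
            raise ValueError("names and active flags must match the number of pairs")

    def __len__(self) -> int:
        return self.moving.shape[0]

    def active_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.moving[self.active], self.reference[self.active]

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path, header=None)
        if df.shape[1] != 8:
            raise ValueError(f"{path}: expected 8 columns (name, active, moving xyz, fixed xyz)")
        active = df[1].astype(str).str.strip().str.lower().isin(("true", "1"))
        return cls(
            moving=df[[2, 3, 4]].to_numpy(dtype=float),
            reference=df[[5, 6, 7]].to_numpy(dtype=float),
            names=[str(v) for v in df[0]],
            active=active.to_numpy(),
        )

    def to_csv(self, path) -> None:
        rows = []
        for i in range(len(self)):
            rows.append(
                [self.names[i], "true" if self.active[i] else "false"]
                + list(self.moving[i])
                + list(self.reference[i])
            )
        pd.DataFrame(rows).to_csv(path, header=False, index=False)


@dataclass
class RigidTransform3D:
    """Rotation + translation mapping moving physical coords to reference coords."""

    R: np.ndarray  # (3, 3)
    t: np.ndarray  # (3,) µm, (x, y, z)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(self.R), 1.0, atol=1e-8
        ):
            raise ValueError("R must be a proper rotation (orthogonal, det +1)")

    def apply(self, points_xyz: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points_xyz) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform3D":
        return RigidTransform3D(R=self.R.T, t=-self.R.T @ self.t)

    def rotation_angle_deg(self) -> float:
        cos = np.clip((np.trace(self.R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)))

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(R=np.eye(3), t=np.zeros(3))


def fit_rigid(landmarks: LandmarkSet) -> tuple[RigidTransform3D, dict]:
    """Least-squares rigid transform minimizing sum ||R m_i + t - r_i||^2.

    Closed-form solution: center both point sets on their centroids, take
    the SVD of the cross-covariance, correct the rotation determinant, and
    recover the translation from the centroids.
    """
    m, r = landmarks.active_pairs()
    n = m.shape[0]
    if n < 3:
        raise DegenerateLandmarksError(f"rigid fit needs >= 3 active landmark pairs, got {n}")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    spread = np.linalg.svd(m0, compute_uv=False)
    if spread[1] < 1e-9 * max(spread[0], 1.0):
        raise DegenerateLandmarksError("active moving landmarks are collinear; the rotation is not determined")
    H = m0.T @ r0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    xform = RigidTransform3D(R=R, t=t)
    if n < 10:
        logger.info("fit_rigid: %d landmarks (10-20 recommended for stable fits)", n)
    residuals, rms = landmark_residuals(landmarks, xform)
    report = {
        "n_active": int(n),
        "rms_um": rms,
        "max_residual_um": float(residuals.max()),
        "rotation_angle_deg": xform.rotation_angle_deg(),
        "translation_um": xform.t.tolist(),
    }
    return xform, report


def landmark_residuals(landmarks: LandmarkSet, xform: RigidTransform3D) -> tuple[np.ndarray, float]:
    """Per-active-pair residual ``||R m_i + t - r_i||`` in µm, and the RMS."""
    m, r = landmarks.active_pairs()
    res = np.linalg.norm(xform.apply(m) - r, axis=1)
    rms = float(np.sqrt(np.mean(res**2))) if res.size else 0.0
    return res, rms


def resample_volume(
    moving: Stack5D,
    xform: RigidTransform3D,
    reference_extents: tuple[int, int, int] | None = None,
    reference_voxel_size: tuple[float, float, float] | None = None,
) -> Stack5D:
    """Resample the moving stack onto the reference grid through the transform.

    Each reference voxel center (in physical µm) is pulled back through the
    inverse transform and the moving volume is sampled there by trilinear
    interpolation, channel by channel; points outside the moving volume are 0.
    """
    nz, ny, nx = reference_extents or (moving.n_z, moving.shape[3], moving.shape[4])
    vz, vy, vx = reference_voxel_size or moving.voxel_size
    mz, my, mx = moving.voxel_size
    inv = xform.inverse()
    zz, yy, xx = np.meshgrid(np.arange(nz) * vz, np.arange(ny) * vy, np.arange(nx) * vx, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    mov_xyz = inv.apply(pts)
    coords = np.stack([mov_xyz[:, 2] / mz, mov_xyz[:, 1] / my, mov_xyz[:, 0] / mx], axis=0).reshape(
        3, nz, ny, nx
    )
    out = np.zeros((moving.n_t, nz, moving.n_c, ny, nx), dtype=np.float64)
    for t in range(moving.n_t):
        for c in range(moving.n_c):
            out[t, :, c] = ndimage.map_coordinates(
                np.asarray(moving.data[t, :, c], dtype=np.float64),
                coords,
                order=1,
                mode="constant",
                cval=0.0,
            )
    if moving.is_float:
        data = out.astype(np.float32)
    else:
        data = np.clip(np.floor(out + 0.5), 0, 2**moving.bit_depth - 1).astype(moving.data.dtype)
    return moving.with_data(data, voxel_size=(vz, vy, vx))


def register_serial(
    moving: Stack5D, reference: Stack5D, landmarks: LandmarkSet
) -> tuple[Stack5D, dict]:
    """Fit the rigid transform from landmarks and resample into the reference grid."""
    xform, report = fit_rigid(landmarks)
    aligned = resample_volume(
        moving,
        xform,
        reference_extents=(reference.n_z, reference.shape[3], reference.shape[4]),
        reference_voxel_size=reference.voxel_size,
    )
    report = dict(report)
    report["rotation_matrix"] = xform.R.tolist()
    return aligned, report


# ---------------------------------------------------------------------------
# translation-only replicate alignment
# ---------------------------------------------------------------------------

def _cross_correlate_offset(ref: np.ndarray, mov: np.ndarray, max_frac: float = 0.5) -> np.ndarray:
    """Offset (z, y, x) by which ``mov`` is displaced relative to ``ref``.

    True normalized cross-correlation over the overlap region at every
    candidate shift, computed with zero-padded FFT correlations of the
    images, their squares and their support masks; unlike plain circular
    correlation this is unbiased for shifts that are a sizeable fraction of
    a short axis.  The integer peak (restricted to ``max_frac`` of each
    extent) is refined per axis by a quadratic fit through its neighbors.
    """
    from scipy import fft as sp_fft

    shape = ref.shape
    full = [sp_fft.next_fast_len(2 * n - 1) for n in shape]

    def corr(x, y):
        fx = sp_fft.rfftn(x, full)
        fy = sp_fft.rfftn(y[tuple(slice(None, None, -1) for _ in shape)], full)
        return sp_fft.irfftn(fx * fy, full)

    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(mov, dtype=np.float64)
    one = np.ones(shape)
    n_ov = corr(one, one)
    s_ab = corr(a, b)
    s_a, s_b = corr(a, one), corr(one, b)
    s_aa, s_bb = corr(a * a, one), corr(one, b * b)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = s_ab - s_a * s_b / n_ov
        var_a = s_aa - s_a**2 / n_ov
        var_b = s_bb - s_b**2 / n_ov
        ncc = num / np.sqrt(np.maximum(var_a, 0) * np.maximum(var_b, 0))
    ncc = np.nan_to_num(ncc, nan=-np.inf)

    # lag s along an axis of length n lives at index (n - 1) + s in the full
    # correlation; keep |s| <= max_frac * n
    windows, lags = [], []
    for ax, n in enumerate(shape):
        m = max(1, int(max_frac * n))
        idx = (np.arange(-m, m + 1) + (n - 1)) % full[ax]
        windows.append(idx)
        lags.append(np.arange(-m, m + 1))
    sub = ncc[np.ix_(*windows)]
    peak = np.array(np.unravel_index(np.argmax(sub), sub.shape))
    offset = np.empty(3)
    for ax in range(3):
        p = peak[ax]
        if 0 < p < sub.shape[ax] - 1:
            sel = [slice(q, q + 1) for q in peak]
            sel[ax] = slice(p - 1, p + 2)
            c0, c1, c2 = sub[tuple(sel)].ravel()
            denom = c0 - 2 * c1 + c2
            frac = 0.0 if abs(denom) < 1e-12 else float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
        else:
            frac = 0.0
        offset[ax] = lags[ax][p] + frac
    # the NCC lag of best overlap is where mov aligns to ref, i.e. minus the
    # displacement that was applied to mov
    return -offset


def align_replicates_translation(replicates: list[Stack5D]) -> tuple[list[Stack5D], np.ndarray]:
    """Align replicate volumes to the first by a single 3D translation each.

    The offset is estimated on the channel-summed volume by normalized
    cross-correlation (integer peak plus quadratic sub-voxel refinement) and
    removed with trilinear interpolation.  Returns the aligned stacks and
    the per-replicate (z, y, x) offsets in voxels.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    geom = replicates[0].shape
    for i, rep in enumerate(replicates):
        if rep.shape != geom:
            raise ValueError(f"replicate {i} has shape {rep.shape}, expected {geom}")
    ref = np.asarray(replicates[0].data[0].sum(axis=1), dtype=np.float64)  # (z, y, x)
    offsets = np.zeros((len(replicates), 3))
    aligned = [replicates[0]]
    for i, rep in enumerate(replicates[1:], start=1):
        mov = np.asarray(rep.data[0].sum(axis=1), dtype=np.float64)
        offsets[i] = _cross_correlate_offset(ref, mov)
        if np.allclose(offsets[i], 0):
            aligned.append(rep)
            continue
        shifted = np.empty_like(rep.data, dtype=np.float64)
        for t in range(rep.n_t):
            for c in range(rep.n_c):
                shifted[t, :, c] = ndimage.shift(
                    np.asarray(rep.data[t, :, c], dtype=np.float64),
                    -offsets[i],
                    order=1,
                    mode="nearest",
                )
        if rep.is_float:
            data = shifted.astype(np.float32)
        else:
            data = np.clip(np.floor(shifted + 0.5), 0, 2**rep.bit_depth - 1).astype(rep.data.dtype)
        aligned.append(rep.with_data(data))
    return aligned, offsets
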