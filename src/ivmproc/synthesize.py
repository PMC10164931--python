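"""Synthetic phantoms with the statistical structure of kidney intravital data.

The generator emulates the three detection channels of a 2-photon kidney
recording: a sparse endothelial network (thin random-walk filaments, the
bright fluorescent-protein channel), tubular autofluorescence (hollow tube
walls plus small bright puncta emulating lysosomes) and capsule collagen
fibrils (oriented filaments confined to the top slices, the weak
second-harmonic channel).  Corruption follows the mixed Poisson-Gaussian
detector model ``z = alpha * Poisson(y) + N(mu, sigma^2)``; drift and
inter-session rigid motion/shrinkage reproduce the registration scenarios.

All generators are pure functions of (spec, seed): the same inputs yield
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_io import Stack5D
from .denoise import PoissonGaussianModel

__all__ = [
    "PhantomSpec",
    "DriftTrajectory",
    "SessionTransform",
    "make_phantom",
    "corrupt",
    "inject_drift",
    "make_serial_pair",
    "make_validation_replicates",
]

_RECIPES = ("endothelial", "tubules", "fibrils")
_CHANNEL_NAMES = {"endothelial": "endothelium", "tubules": "tubules", "fibrils": "capsule"}


@dataclass
class PhantomSpec:
    """Recipe for one synthetic multichannel volume.

    Default extents echo the validation-dataset geometry (25 replicates of a
    45-slice volume, three channels), with the lateral size reduced to
    256x256 for desk-scale runs.  Intensities are in ADU; the fibril channel
    is deliberately the weakest so it plays the role of the lowest-SNR
    channel.  ``decay_tau_s`` optionally applies a mono-exponential intensity
    decay over time to a channel (a vascular tracer wash-out analogue).
    """

    shape: tuple[int, int, int, int, int] = (25, 45, 3, 256, 256)
    voxel_size: tuple[float, float, float] = (1.0, 0.58, 0.58)
    frame_interval_s: float = 5.0
    background: float = 25.0
    amp_endothelial: float = 350.0
    amp_tubule: float = 250.0
    amp_puncta: float = 600.0
    amp_fibril: float = 120.0
    n_filaments: int | None = None  # None: scaled from the lateral area (12 at 256^2)
    n_tubes: int | None = None  # 4 at 256^2
    n_puncta: int | None = None  # 30 at 256^2
    n_fibrils: int | None = None  # 20 at 256^2
    filament_radius_px: float = 5.0  # capillary half-width (~6 µm diameter at 0.58 µm/px)
    tube_wall_px: float = 2.5  # half-thickness of tubule walls
    decay_tau_s: dict = field(default_factory=dict)  # channel index -> tau (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 5 or any(e < 1 for e in self.shape):
            raise ValueError(f"extents must be five values >= 1, got {self.shape}")
        for a in (self.amp_endothelial, self.amp_tubule, self.amp_puncta, self.amp_fibril, self.background):
            if a < 0:
                raise ValueError("intensity values must be non-negative")
        # structure counts not given explicitly scale with the lateral area so
        # density (and hence feature richness) is resolution-independent
        area = self.shape[3] * self.shape[4] / (256.0 * 256.0)
        if self.n_filaments is None:
            self.n_filaments = max(2, round(12 * area))
        if self.n_tubes is None:
            self.n_tubes = max(1, round(4 * area))
        if self.n_puncta is None:
            self.n_puncta = max(3, round(30 * area))
        if self.n_fibrils is None:
            self.n_fibrils = max(3, round(20 * area))

    def channel_recipes(self) -> list[str]:
        c = self.shape[2]
        return [_RECIPES[i % len(_RECIPES)] for i in range(c)]


@dataclass
class DriftTrajectory:
    """Per-frame lateral shifts (dx, dy) in pixels, sub-pixel allowed."""

    shifts: np.ndarray  # (n, 2) as (dx, dy)
    onset: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be an (n, 2) array of (dx, dy)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")

    def __len__(self) -> int:
        return self.shifts.shape[0]

    @classmethod
    def gradual(
        cls,
        n_frames: int,
        onset: int,
        drift_per_frame: tuple[float, float] = (0.4, -0.25),
        jitter: float = 0.0,
        seed: int = 0,
    ) -> "DriftTrajectory":
        """Zero shift before ``onset``, then linearly accumulating drift.

        Emulates a recording that is stable early on and then starts to
        drift gradually; ``jitter`` adds per-frame Gaussian wobble on top.
        """
        rng = np.random.default_rng(seed)
        shifts = np.zeros((n_frames, 2))
        after = np.arange(n_frames) - onset
        ramp = np.clip(after, 0, None).astype(float)
        shifts[:, 0] = ramp * drift_per_frame[0]
        shifts[:, 1] = ramp * drift_per_frame[1]
        if jitter > 0:
            shifts += rng.normal(0.0, jitter, shifts.shape)
            shifts[:onset] = 0.0
        return cls(shifts, onset=onset)


@dataclass
class SessionTransform:
    """Rigid motion (+ optional anisotropic shrink) between imaging sessions."""

    rot_z_deg: float = 0.0
    rot_y_deg: float = 0.0
    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)
    shrink: tuple[float, float, float] = (1.0, 1.0, 1.0)  # per (x, y, z), in (0, 1]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rot_z_deg) and np.isfinite(self.rot_y_deg)):
            raise ValueError("rotation angles must be finite")
        if any(not (0 < s <= 1) for s in self.shrink):
            raise ValueError(f"shrink factors must be in (0, 1], got {self.shrink}")

    def rotation(self) -> np.ndarray:
        az, ay = np.deg2rad(self.rot_z_deg), np.deg2rad(self.rot_y_deg)
        rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
        return rz @ ry

    def apply(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map moving-session physical coordinates to reference coordinates."""
        p = np.asarray(points_xyz, dtype=np.float64) * np.asarray(self.shrink)
        return p @ self.rotation().T + np.asarray(self.translation_um)

    def invert_points(self, points_xyz: np.ndarray) -> np.ndarray:
        p = (np.asarray(points_xyz, dtype=np.float64) - np.asarray(self.translation_um)) @ self.rotation()
        return p / np.asarray(self.shrink)


# ---------------------------------------------------------------------------
# structure rasterizers
# ---------------------------------------------------------------------------

def _deposit_walk(vol: np.ndarray, rng, n_walks: int, step: float, wiggle: float, z_band=None) -> None:
    nz, ny, nx = vol.shape
    n_steps = int(2.5 * max(ny, nx) / step)
    for _ in range(n_walks):
        if z_band is None:
            pos = np.array([rng.uniform(0, nz), rng.uniform(0, ny), rng.uniform(0, nx)])
            d = rng.normal(size=3)
            d[0] *= 0.3  # filaments run mostly laterally
        else:
            pos = np.array([rng.uniform(*z_band), rng.uniform(0, ny), rng.uniform(0, nx)])
            theta = rng.normal(np.deg2rad(30.0), np.deg2rad(12.0))  # preferred fibril orientation
            d = np.array([rng.normal(0, 0.05), np.sin(theta), np.cos(theta)])
        d /= np.linalg.norm(d)
        for _ in range(n_steps):
            pos += d * step
            if z_band is not None:
                pos[0] = np.clip(pos[0], z_band[0], z_band[1] - 1e-9)
            if not (0 <= pos[0] < nz and 0 <= pos[1] < ny and 0 <= pos[2] < nx):
                break
            iz, iy, ix = (int(round(v)) for v in pos)
            vol[min(iz, nz - 1), min(iy, ny - 1), min(ix, nx - 1)] = 1.0
            turn = rng.normal(0, wiggle, 3)
            if z_band is not None:
                turn[0] *= 0.2
            d = d + turn
            d /= np.linalg.norm(d)


def _endothelial_channel(shape, rng, spec: PhantomSpec) -> np.ndarray:
    vol = np.zeros(shape)
    _deposit_walk(vol, rng, spec.n_filaments, step=0.7, wiggle=0.15)
    # vessels are filled, flat-topped structures: dilate the centerline to the
    # capillary radius (anisotropic in z) and soften the rim like a PSF would
    r = spec.filament_radius_px
    dist = ndimage.distance_transform_edt(vol == 0, sampling=(2.0, 1.0, 1.0))
    vol = (dist <= r).astype(np.float64)
    vol = ndimage.gaussian_filter(vol, 1.0)
    if vol.max() > 0:
        vol *= spec.amp_endothelial / vol.max()
    return vol


def _tubule_channel(shape, rng, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = shape
    center = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_tubes):
        pos = np.array([rng.uniform(0.25 * nz, 0.75 * nz), rng.uniform(0, ny), rng.uniform(0, nx)])
        ang = rng.uniform(0, 2 * np.pi)
        d = np.array([rng.normal(0, 0.05), np.sin(ang), np.cos(ang)])
        d /= np.linalg.norm(d)
        for _ in range(int(2.0 * max(ny, nx))):
            pos += d
            if not (0 <= pos[0] < nz and 0 <= pos[1] < ny and 0 <= pos[2] < nx):
                break
            center[int(pos[0]), int(pos[1]), int(pos[2])] = True
            d = d + rng.normal(0, 0.04, 3) * np.array([0.3, 1, 1])
            d /= np.linalg.norm(d)
    tube_r = max(3.0, min(ny, nx) / 8.0)
    dist = ndimage.distance_transform_edt(~center)
    wall = (np.abs(dist - tube_r) <= spec.tube_wall_px).astype(np.float64)
    wall = ndimage.gaussian_filter(wall, 1.0)
    if wall.max() > 0:
        wall *= spec.amp_tubule / wall.max()

    # bright puncta (lysosome analogues): well separated Gaussian blobs that
    # stand clear of the tube walls so they are countable as local maxima
    puncta = np.zeros(shape)
    margin, min_sep = 5, 7.0
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < spec.n_puncta and tries < 20000:
        tries += 1
        cand = np.array(
            [
                rng.uniform(margin, nz - margin) if nz > 2 * margin else nz / 2,
                rng.uniform(margin, ny - margin),
                rng.uniform(margin, nx - margin),
            ]
        )
        if centers and np.min(np.linalg.norm(np.array(centers) - cand, axis=1)) < min_sep:
            continue
        centers.append(cand)
    if len(centers) < spec.n_puncta:
        raise ValueError(f"could not place {spec.n_puncta} puncta with separation {min_sep}")
    for c in centers:
        puncta[tuple(int(round(v)) for v in np.minimum(c, np.array(shape) - 1))] = 1.0
    puncta = ndimage.gaussian_filter(puncta, 1.3)
    if puncta.max() > 0:
        puncta *= spec.amp_puncta / puncta.max()
    return wall, puncta


def _fibril_channel(shape, rng, spec: PhantomSpec) -> np.ndarray:
    nz = shape[0]
    band = (0.0, max(2.0, 0.15 * nz))
    vol = np.zeros(shape)
    _deposit_walk(vol, rng, spec.n_fibrils, step=0.7, wiggle=0.02, z_band=band)
    vol = ndimage.gaussian_filter(vol, (0.6, 0.9, 0.9))
    if vol.max() > 0:
        vol *= spec.amp_fibril / vol.max()
    return vol


def make_phantom(spec: PhantomSpec) -> Stack5D:
    """Noise-free floating-point phantom stack, deterministic given the seed."""
    nt, nz, nc, ny, nx = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    vol_shape = (nz, ny, nx)
    channels = []
    names = []
    for c, recipe in enumerate(spec.channel_recipes()):
        if recipe == "endothelial":
            vol = _endothelial_channel(vol_shape, rng, spec)
        elif recipe == "tubules":
            wall, puncta = _tubule_channel(vol_shape, rng, spec)
            vol = np.maximum(wall, puncta)
        else:
            vol = _fibril_channel(vol_shape, rng, spec)
        channels.append(vol)
        names.append(_CHANNEL_NAMES[recipe])
    static = np.stack(channels, axis=0)  # (c, z, y, x)

    data = np.empty(spec.shape, dtype=np.float32)
    times = np.arange(nt) * spec.frame_interval_s
    for c in range(nc):
        tau = spec.decay_tau_s.get(c)
        factors = np.exp(-times / tau) if tau else np.ones(nt)
        for t in range(nt):
            data[t, :, c] = spec.background + factors[t] * static[c]
    return Stack5D(
        data,
        voxel_size=spec.voxel_size,
        frame_interval=spec.frame_interval_s,
        bit_depth=32,
        channel_names=names,
        is_float=True,
    )


# ---------------------------------------------------------------------------
# corruption and motion
# ---------------------------------------------------------------------------

def corrupt(
    stack: Stack5D, model: PoissonGaussianModel, seed: int = 0, bit_depth: int = 16
) -> Stack5D:
    """Apply mixed Poisson-Gaussian noise: ``z = alpha * Poisson(y/alpha) + N(mu, sigma^2)``.

    The clean stack holds the expected signal in ADU, so the Poisson mean in
    photon units is ``y/alpha``; the draw is scaled back by the gain and the
    additive Gaussian read noise is added.  ``E[z] = y + mu`` and
    ``Var[z] = alpha*y + sigma^2``.  Output is quantized to ``bit_depth``.
    """
    clean = np.asarray(stack.data, dtype=np.float64)
    if clean.min() < 0:
        raise ValueError("corrupt expects a non-negative clean stack")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    photons = rng.poisson(clean / model.alpha).astype(np.float64)
    z = model.alpha * photons + rng.normal(model.mu, model.sigma, clean.shape)
    hi = 2**bit_depth - 1
    data = np.clip(np.floor(z + 0.5), 0, hi).astype(np.uint8 if bit_depth == 8 else np.uint16)
    return stack.with_data(data, bit_depth=bit_depth, is_float=False)


def inject_drift(
    stack: Stack5D, traj: DriftTrajectory, axis: str = "t"
) -> tuple[Stack5D, DriftTrajectory]:
    """Translate frame i laterally by ``traj.shifts[i]`` (bilinear, zero fill).

    ``axis`` selects the frame axis ('t' for time series, 'z' for per-slice
    jitter in volumes).  The ground-truth trajectory is returned alongside
    for oracle checks.
    """
    n = stack.n_t if axis == "t" else stack.n_z
    if axis not in ("t", "z"):
        raise ValueError("axis must be 't' or 'z'")
    if len(traj) != n:
        raise ValueError(f"trajectory has {len(traj)} entries for {n} frames along {axis}")
    out = np.array(stack.data, dtype=np.float64)
    for i, (dx, dy) in enumerate(traj.shifts):
        if dx == 0 and dy == 0:
            continue
        sel = (i, slice(None)) if axis == "t" else (slice(None), i)
        frames = out[sel]  # (z|t, c, y, x)
        out[sel] = ndimage.shift(frames, (0, 0, dy, dx), order=1, mode="constant", cval=0.0)
    if stack.is_float:
        data = out.astype(np.float32)
    else:
        data = np.clip(np.floor(out + 0.5), 0, 2**stack.bit_depth - 1).astype(stack.data.dtype)
    return stack.with_data(data), traj


# ---------------------------------------------------------------------------
# serial sessions and validation replicates
# ---------------------------------------------------------------------------

def _single_timepoint(spec: PhantomSpec) -> Stack5D:
    one = replace(spec, shape=(1,) + tuple(spec.shape[1:]))
    return make_phantom(one)


def make_serial_pair(
    spec: PhantomSpec, xform: SessionTransform, n_landmarks: int = 15
):
    """Reference and moving volumes of a serial-imaging session pair.

    The moving volume is the reference resampled through the session
    transform (plus optional anisotropic shrink); landmark pairs are exact
    correspondences sampled on bright structures.  When the shrink factors
    are 1 the returned :class:`~ivmproc.register3d.RigidTransform3D` is the
    exact moving-to-reference mapping, so fitting the landmarks recovers it.
    """
    from .register3d import LandmarkSet, RigidTransform3D

    reference = _single_timepoint(spec)
    nz, ny, nx = reference.n_z, reference.shape[3], reference.shape[4]
    vz, vy, vx = reference.voxel_size

    # pull resampling: moving voxel center -> physical -> reference coords
    zz, yy, xx = np.meshgrid(np.arange(nz) * vz, np.arange(ny) * vy, np.arange(nx) * vx, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    ref_xyz = xform.apply(pts)
    coords = np.stack(
        [ref_xyz[:, 2] / vz, ref_xyz[:, 1] / vy, ref_xyz[:, 0] / vx], axis=0
    ).reshape(3, nz, ny, nx)
    moving_data = np.empty_like(reference.data)
    for c in range(reference.n_c):
        moving_data[0, :, c] = ndimage.map_coordinates(
            np.asarray(reference.data[0, :, c], dtype=np.float64),
            coords,
            order=1,
            mode="constant",
            cval=0.0,
        )
    moving = reference.with_data(moving_data)

    # landmarks on bright structures of the reference, mapped back into the
    # moving volume; rejection-sample until all pairs are in bounds
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 303]))
    vol = np.max(reference.data[0], axis=1)  # (z, y, x) max over channels
    thresh = spec.background + 0.25 * max(vol.max() - spec.background, 1e-9)
    cand = np.argwhere(vol > thresh)
    if cand.shape[0] < n_landmarks:
        raise ValueError("phantom too sparse to sample the requested number of landmarks")
    ref_pts, mov_pts = [], []
    order = rng.permutation(cand.shape[0])
    lim = np.array([(nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz])
    for idx in order:
        iz, iy, ix = cand[idx]
        r = np.array([ix * vx, iy * vy, iz * vz])
        m = xform.invert_points(r[None, :])[0]
        if np.all(m >= 0) and np.all(m <= lim):
            ref_pts.append(r)
            mov_pts.append(m)
        if len(ref_pts) == n_landmarks:
            break
    if len(ref_pts) < n_landmarks:
        raise ValueError("could not place the requested landmarks inside both volumes")

    landmarks = LandmarkSet(moving=np.array(mov_pts), reference=np.array(ref_pts))
    true_xform = RigidTransform3D(R=xform.rotation(), t=np.asarray(xform.translation_um, dtype=float))
    return reference, moving, landmarks, true_xform


def make_validation_replicates(
    spec: PhantomSpec,
    n: int = 25,
    model: PoissonGaussianModel | None = None,
    jitter_um: float = 0.5,
    seed: int = 0,
):
    """Noisy replicates of one volume plus the clean ground truth and true offsets.

    Each replicate is the clean phantom shifted by a small random 3D offset
    (at most ``jitter_um`` per axis, emulating residual inter-replicate
    drift) and then corrupted with the Poisson-Gaussian model.  Returns
    ``(replicates, clean, offsets_vox)`` with offsets as (z, y, x) voxels.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    model = model or PoissonGaussianModel(alpha=4.0, sigma=10.0, mu=0.0)
    clean = _single_timepoint(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    offsets_um = rng.uniform(-jitter_um, jitter_um, size=(n, 3)) if jitter_um > 0 else np.zeros((n, 3))
    offsets_vox = offsets_um / np.asarray(clean.voxel_size)
    reps = []
    for i in range(n):
        if np.any(offsets_vox[i]):
            shifted = np.empty_like(clean.data)
            for c in range(clean.n_c):
                shifted[0, :, c] = ndimage.shift(
                    np.asarray(clean.data[0, :, c], dtype=np.float64),
                    offsets_vox[i],
                    order=1,
                    mode="nearest",
                )
            rep_clean = clean.with_data(shifted)
        else:
            rep_clean = clean
        reps.append(corrupt(rep_clean, model, seed=int(seed) * 1000 + i))
    return reps, clean, offsets_vox
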