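"""Calibrated 5D image stacks and TIFF/OME-TIFF input-output.

Every stage of the toolbox consumes and produces :class:`Stack5D`, a
multichannel volume/time-series with a fixed canonical axis order
``(t, z, c, y, x)`` and physical calibration (voxel size in µm, frame
interval in seconds).  Index 0 is the first voxel and physical position
equals ``index * voxel_size``; one convention everywhere avoids sign bugs
in the registration stages.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("ivmproc")

CANONICAL_AXES = "TZCYX"

__all__ = [
    "Stack5D",
    "AxisOrder",
    "FormatError",
    "AxisAmbiguityError",
    "read_stack",
    "write_stack",
    "split_channels",
    "merge_channels",
    "quantize_to_uint",
    "reslice_xz",
]


class FormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


class AxisAmbiguityError(FormatError):
    """Raised when the storage axis order cannot be inferred and no hint is given."""


def _dtype_for(bit_depth: int, is_float: bool) -> np.dtype:
    if is_float:
        return np.dtype(np.float32)
    return {8: np.dtype(np.uint8), 16: np.dtype(np.uint16), 32: np.dtype(np.uint32)}[bit_depth]


@dataclass
class Stack5D:
    """A calibrated multichannel image stack indexed ``(t, z, c, y, x)``.

    Parameters
    ----------
    data:
        Intensity array in ADU (analog-digital units) with exactly five axes.
    voxel_size:
        Physical voxel extents ``(z, y, x)`` in µm/voxel; all positive.
    frame_interval:
        Seconds between time points; 0 when there is no meaningful time axis.
    bit_depth:
        8, 16 or 32.  Integer stacks must hold values in
        ``[0, 2**bit_depth - 1]``.
    channel_names:
        One label per channel.
    is_float:
        True for 32-bit floating point intermediates (denoising, registration
        channels) where the integer range invariant does not apply.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 0.0
    bit_depth: int = 16
    channel_names: list[str] = field(default_factory=list)
    is_float: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"Stack5D data must have 5 axes (t, z, c, y, x), got {self.data.ndim}")
        if any(e < 1 for e in self.data.shape):
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats (z, y, x), got {self.voxel_size}")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError(f"bit_depth must be 8, 16 or 32, got {self.bit_depth}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[2])]
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for C={self.data.shape[2]}"
            )
        if not self.is_float:
            hi = 2**self.bit_depth - 1
            mn, mx = float(self.data.min()), float(self.data.max())
            if mn < 0 or mx > hi:
                raise ValueError(
                    f"integer stack holds values in [{mn}, {mx}] outside [0, {hi}] "
                    f"for bit_depth {self.bit_depth}"
                )
        target = _dtype_for(self.bit_depth, self.is_float)
        if self.data.dtype != target:
            self.data = self.data.astype(target)

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.data.shape

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def n_c(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **overrides) -> "Stack5D":
        """Copy of this stack with new pixel data (and optional field overrides)."""
        kw = dict(
            voxel_size=self.voxel_size,
            frame_interval=self.frame_interval,
            bit_depth=self.bit_depth,
            channel_names=list(self.channel_names),
            is_float=self.is_float,
        )
        kw.update(overrides)
        if kw.get("is_float") != self.is_float and "bit_depth" not in overrides:
            kw["bit_depth"] = 32 if kw["is_float"] else self.bit_depth
        return Stack5D(data, **kw)

    def copy(self) -> "Stack5D":
        return self.with_data(self.data.copy())


@dataclass(frozen=True)
class AxisOrder:
    """Mapping from file storage order to the canonical ``TZCYX`` order.

    ``axes`` names the stored dimensions in storage order using characters
    from ``TZCYX`` (e.g. ``"ZCYX"`` for a z-stack stored plane-major with
    interleaved channels).  Absent axes are assigned extent 1.
    """

    axes: str

    def __post_init__(self) -> None:
        ax = self.axes.upper()
        if len(set(ax)) != len(ax) or any(a not in CANONICAL_AXES for a in ax):
            raise ValueError(f"axes must be a subset permutation of {CANONICAL_AXES}, got {self.axes!r}")
        object.__setattr__(self, "axes", ax)

    def to_canonical(self, arr: np.ndarray) -> np.ndarray:
        if arr.ndim != len(self.axes):
            raise ValueError(f"array has {arr.ndim} axes but order {self.axes!r} names {len(self.axes)}")
        full = arr.reshape(arr.shape + (1,) * (5 - arr.ndim))
        order = self.axes + "".join(a for a in CANONICAL_AXES if a not in self.axes)
        perm = [order.index(a) for a in CANONICAL_AXES]
        return np.ascontiguousarray(full.transpose(perm))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _parse_ome(xml_text: str) -> dict:
    """Extract calibration and channel names from OME-XML; missing fields omitted."""
    out: dict = {}
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return out
    ns = root.tag.partition("}")[0] + "}" if root.tag.startswith("{") else ""
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return out
    vs = []
    for key, default in (("PhysicalSizeZ", None), ("PhysicalSizeY", None), ("PhysicalSizeX", None)):
        v = pixels.get(key, default)
        vs.append(float(v) if v is not None else None)
    if all(v is not None for v in vs):
        out["voxel_size"] = tuple(vs)
    ti = pixels.get("TimeIncrement")
    if ti is not None:
        out["frame_interval"] = float(ti)
    names = [ch.get("Name") for ch in pixels.findall(f"{ns}Channel")]
    if names and all(n is not None for n in names):
        out["channel_names"] = names
    return out


def read_stack(path, axis_hint: AxisOrder | None = None) -> Stack5D:
    """Read a TIFF or OME-TIFF file into a canonical :class:`Stack5D`.

    Calibration is taken from OME metadata when present, else from a JSON
    sidecar (``<file>.tif.json``), else defaults to 1 µm voxels and a 0 s
    frame interval with a logged warning.  Plain multi-page TIFFs whose axis
    order cannot be inferred require ``axis_hint``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cannot read image file: {path} does not exist")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            file_axes = series.axes.upper()
            ome_xml = tif.ome_metadata
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises a mix of types for bad files
        raise FormatError(f"cannot read image file {path}: {exc}") from exc

    meta: dict = {}
    if ome_xml:
        meta = _parse_ome(ome_xml)
    sidecar = _sidecar_path(path)
    if not meta and sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if "voxel_size_um" in raw:
            meta["voxel_size"] = tuple(raw["voxel_size_um"])
        if "frame_interval_s" in raw:
            meta["frame_interval"] = float(raw["frame_interval_s"])
        if "channel_names" in raw:
            meta["channel_names"] = list(raw["channel_names"])
        if "axes" in raw and axis_hint is None:
            axis_hint = AxisOrder(raw["axes"])

    if axis_hint is not None:
        data = axis_hint.to_canonical(arr)
    else:
        known = "".join(a for a in file_axes if a in CANONICAL_AXES)
        if len(known) != len(file_axes):
            # tifffile reports unidentified page axes as Q/I/S; a bare 3D
            # multipage file could be T, Z or C and needs a hint.
            unknown = [a for a in file_axes if a not in CANONICAL_AXES]
            if arr.ndim <= 2:
                data = AxisOrder("YX"[-arr.ndim:] or "X").to_canonical(arr)
            elif len(unknown) == 1 and arr.ndim == 3:
                raise AxisAmbiguityError(
                    f"{path}: cannot tell whether the page axis of a plain multi-page TIFF "
                    "is T, Z or C; pass axis_hint or provide a JSON sidecar with an 'axes' key"
                )
            else:
                raise AxisAmbiguityError(f"{path}: ambiguous storage axes {file_axes!r}; pass axis_hint")
        else:
            data = AxisOrder(known).to_canonical(arr)

    if "voxel_size" not in meta:
        logger.warning("%s: no calibration found; defaulting to 1 µm voxels, 0 s interval", path)
    is_float = np.issubdtype(data.dtype, np.floating)
    bit_depth = 32 if is_float else int(data.dtype.itemsize * 8)
    return Stack5D(
        data,
        voxel_size=meta.get("voxel_size", (1.0, 1.0, 1.0)),
        frame_interval=meta.get("frame_interval", 0.0),
        bit_depth=bit_depth,
        channel_names=meta.get("channel_names", []),
        is_float=is_float,
    )


def write_stack(stack: Stack5D, path) -> None:
    """Write a stack as OME-TIFF preserving axes, calibration and channel names.

    ``read_stack(write_stack(s)) == s`` on data and calibration.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write {path}: parent directory does not exist")
    # validation (integer range etc.) happens in the constructor; re-run it so
    # callers that mutated .data in place cannot write invalid files
    stack = Stack5D(
        stack.data,
        voxel_size=stack.voxel_size,
        frame_interval=stack.frame_interval,
        bit_depth=stack.bit_depth,
        channel_names=stack.channel_names,
        is_float=stack.is_float,
    )
    vz, vy, vx = stack.voxel_size
    metadata = {
        "axes": CANONICAL_AXES,
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": list(stack.channel_names)},
    }
    if stack.frame_interval:
        metadata["TimeIncrement"] = stack.frame_interval
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, stack.data, ome=True, metadata=metadata, photometric="minisblack")


def split_channels(stack: Stack5D) -> list[Stack5D]:
    """Split into C single-channel stacks; concatenating them restores the input."""
    return [
        stack.with_data(stack.data[:, :, c : c + 1], channel_names=[stack.channel_names[c]])
        for c in range(stack.n_c)
    ]


def merge_channels(stacks: list[Stack5D]) -> Stack5D:
    """Concatenate single-channel stacks along the channel axis."""
    if not stacks:
        raise ValueError("merge_channels needs at least one stack")
    first = stacks[0]
    ref_geom = (first.n_t, first.n_z, first.shape[3], first.shape[4])
    for i, s in enumerate(stacks):
        geom = (s.n_t, s.n_z, s.shape[3], s.shape[4])
        if geom != ref_geom:
            raise ValueError(f"stack {i} has (t,z,y,x) extents {geom}, expected {ref_geom}")
        if s.voxel_size != first.voxel_size or s.bit_depth != first.bit_depth:
            raise ValueError(f"stack {i} differs in voxel size or bit depth from stack 0")
    data = np.concatenate([s.data for s in stacks], axis=2)
    names = [name for s in stacks for name in s.channel_names]
    return first.with_data(data, channel_names=names)


def quantize_to_uint(stack: Stack5D, bit_depth: int = 16) -> Stack5D:
    """Round a 32-bit float stack half-away-from-zero and clip to the uint range.

    Clipping is defined behavior (logged when it occurs), matching the
    convention of rescaling 32-bit denoised output back to unsigned integers.
    """
    if not stack.is_float:
        raise ValueError("quantize_to_uint expects a floating-point stack")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    hi = 2**bit_depth - 1
    rounded = np.copysign(np.floor(np.abs(stack.data.astype(np.float64)) + 0.5), stack.data)
    n_clip = int(np.count_nonzero((rounded < 0) | (rounded > hi)))
    if n_clip:
        logger.info("quantize_to_uint clipped %d values to [0, %d]", n_clip, hi)
    out = np.clip(rounded, 0, hi).astype(_dtype_for(bit_depth, False))
    return stack.with_data(out, bit_depth=bit_depth, is_float=False)


def reslice_xz(stack: Stack5D, t: int, c: int, y: int) -> np.ndarray:
    """Axial cross-section: 2D image with x horizontal and z vertical.

    Pixel ``(z, x)`` of the output equals ``stack.data[t, z, c, y, x]``.
    """
    nt, nz, nc, ny, nx = stack.shape
    for name, idx, n in (("t", t, nt), ("c", c, nc), ("y", y, ny)):
        if not 0 <= idx < n:
            raise IndexError(f"{name} index {idx} out of range [0, {n})")
    return np.asarray(stack.data[t, :, c, y, :])
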