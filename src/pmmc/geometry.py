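"""Voxel grids, Siddon-style ray traversal and material-interface detection.

Coordinates are continuous cm; voxel (i, j, k) spans the half-open box
``[origin + i*spacing, origin + (i+1)*spacing)`` per axis (0-based indices,
origin at the grid corner).  A *material interface* is a boundary between two
voxels whose HU values are separated by a node of the CT ramp — voxels inside
one mixed-material band are not separated, which is what allows macro steps
to span many voxels of varying HU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels as K
from .materials import CTRamp


class OutOfGridError(ValueError):
    """Raised when a point expected inside the grid lies outside it."""


@dataclass
class VoxelGrid:
    """HU volume with spacing/origin metadata.

    ``hu`` has shape (nx, ny, nz); int16 on disk, any integer/float dtype in
    memory.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3 or min(self.hu.shape) < 1:
            raise ValueError("hu must be a 3-D array with all dims >= 1")
        if min(self.spacing) <= 0:
            raise ValueError("all spacings must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.hu.shape, self.spacing))

    def hu_float(self) -> np.ndarray:
        """float64 view used by the compiled kernels (cached)."""
        arr = getattr(self, "_hu_f8", None)
        if arr is None or arr.shape != self.hu.shape:
            arr = np.ascontiguousarray(self.hu, dtype=np.float64)
            self._hu_f8 = arr
        return arr

    def voxel_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = tuple(int(np.floor((p - o) / s))
                    for p, o, s in zip(point, self.origin, self.spacing))
        if not self.contains_index(idx):
            raise OutOfGridError(f"point {tuple(point)} outside grid")
        return idx

    def contains_index(self, idx: Sequence[int]) -> bool:
        return all(0 <= i < n for i, n in zip(idx, self.hu.shape))

    def contains_point(self, point: Sequence[float]) -> bool:
        return all(o <= p < o + n * s for p, o, s, n in
                   zip(point, self.origin, self.spacing, self.hu.shape))

    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class TrackSegment:
    """One voxel cut of a polyline track: cut length d_i plus end points."""

    voxel_index: tuple[int, int, int]
    cut_length: float
    entry_point: tuple[float, float, float]
    exit_point: tuple[float, float, float]


def trace_segments(grid: VoxelGrid, polyline: Sequence[Sequence[float]]
                   ) -> list[TrackSegment]:
    """Voxel-ordered cuts of a polyline; out-of-grid portions are omitted."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (n>=2, 3) point list")
    hu = grid.hu_float()
    nodes = np.array([0.0])  # unused with break_mode 0
    ox, oy, oz = grid.origin
    dx, dy, dz = grid.spacing
    cap = 1 << 16
    seg_vox = np.empty(cap, dtype=np.int64)
    seg_len = np.empty(cap)
    seg_t0 = np.empty(cap)
    out: list[TrackSegment] = []
    ny, nz = grid.hu.shape[1], grid.hu.shape[2]
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        length = float(np.linalg.norm(d))
        if length <= 0:
            continue
        u = d / length
        nseg, _, _, _, _, _ = K.walk_segment(
            hu, nodes, ox, oy, oz, dx, dy, dz,
            p0[0], p0[1], p0[2], u[0], u[1], u[2], length,
            1e30, 0.0, 0, seg_vox, seg_len, seg_t0, 0, 0.0)
        for s in range(nseg):
            v = int(seg_vox[s])
            k = v % nz
            j = (v // nz) % ny
            i = v // (nz * ny)
            t0 = seg_t0[s]
            t1 = t0 + seg_len[s]
            out.append(TrackSegment(
                voxel_index=(i, j, k),
                cut_length=float(seg_len[s]),
                entry_point=tuple(p0 + t0 * u),
                exit_point=tuple(p0 + t1 * u),
            ))
    return out


def is_interface(ramp: CTRamp, hu_a: float, hu_b: float) -> bool:
    """True iff the two HU values lie in different mixed-material bands
    (a ramp node strictly between them; a shared boundary node does not
    separate)."""
    return bool(K.is_interface_k(float(hu_a), float(hu_b), ramp.hu_nodes))


def distance_to_interface(grid: VoxelGrid, ramp: CTRamp,
                          origin: Sequence[float], direction: Sequence[float],
                          max_distance: float) -> float:
    """Raytraced distance d to the next material interface along the ray,
    capped at min(max_distance, distance to grid exit)."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    p = np.asarray(origin, dtype=float)
    d = K.distance_to_interface_k(
        grid.hu_float(), ramp.hu_nodes, *grid.origin, *grid.spacing,
        p[0], p[1], p[2], u[0], u[1], u[2], float(max_distance), False)
    if d < 0:
        raise OutOfGridError(f"origin {tuple(p)} outside grid")
    return float(d)


def lateral_interface_distance(grid: VoxelGrid, ramp: CTRamp,
                               origin: Sequence[float],
                               direction: Sequence[float],
                               step_length: float, radius: float) -> float:
    """Minimum distance from the intended step segment to any voxel in a
    different material band, searched within ``radius`` (returned as sentinel
    when nothing is found)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    p = np.asarray(origin, dtype=float)
    return float(K.lateral_interface_distance_k(
        grid.hu_float(), ramp.hu_nodes, *grid.origin, *grid.spacing,
        p[0], p[1], p[2], u[0], u[1], u[2], float(step_length), float(radius)))


# ---------------------------------------------------------------------------
# volume I/O (MetaImage / NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def write_volume(path, grid: VoxelGrid, array: np.ndarray | None = None) -> None:
    """Write HU (int16) or a co-registered scalar volume to .mha/.mhd/.nrrd."""
    import SimpleITK as sitk

    data = grid.hu.astype(np.int16) if array is None else np.asarray(array)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    # SimpleITK origins address the center of voxel (0,0,0)
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(grid.origin, grid.spacing)))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> VoxelGrid:
    """Read a .mha/.mhd/.nrrd volume into a VoxelGrid (values kept as stored)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    return VoxelGrid(hu=arr, spacing=spacing, origin=origin)


def read_dose(path) -> tuple[np.ndarray, VoxelGrid]:
    g = read_volume(path)
    return np.asarray(g.hu, dtype=float), g


__all__ = [
    "VoxelGrid", "TrackSegment", "OutOfGridError",
    "trace_segments", "is_interface", "distance_to_interface",
    "lateral_interface_distance", "write_volume", "read_volume", "read_dose",
]
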