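"""Validation phantoms and beam definitions.

The academic phantoms consist of an adipose/muscle mixture whose HU value
varies layer by layer (1 mm) inside the single adipose-muscle band of the CT
ramp — so the background contains *no* material interfaces — with lung and
cortical-bone inhomogeneities inserted either in series (transverse slabs
along the beam) or adjacent to each other (side-by-side parallelepipeds
parallel to the beam).  Beams enter at z = 0 travelling in +z; the grid is
centered on the beam axis in x and y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGrid

HU_ADIPOSE = -77
HU_MUSCLE = 40
HU_LUNG = -610
HU_BONE = 1524

# layer-by-layer HU cycle spanning the adipose-muscle band
BACKGROUND_CYCLE = (-77, -38, 1, 40)

# default block extents of the inhomogeneities [cm]
SERIES_LUNG_Z = (4.0, 8.0)
SERIES_BONE_Z = (12.0, 16.0)
ADJACENT_Z = (4.0, 16.0)


@dataclass
class BeamSpec:
    """Pencil or rectangular broad beam."""

    kind: str  # pencil | broad
    energy: float  # MeV
    entry: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    field_size: tuple[float, float] | None = None  # cm x cm, broad only

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if self.kind not in ("pencil", "broad"):
            raise ValueError(f"unknown beam kind {self.kind!r}")
        if self.kind == "broad":
            if self.field_size is None or min(self.field_size) <= 0:
                raise ValueError("broad beams need a positive field size")
        u = np.asarray(self.direction, dtype=float)
        self.direction = tuple(u / np.linalg.norm(u))


def _background(dims: tuple[int, int, int], dz: float) -> np.ndarray:
    nz = dims[2]
    layer = (np.floor(np.arange(nz) * dz / 0.1)).astype(int)  # 1 mm layers
    cyc = np.asarray(BACKGROUND_CYCLE, dtype=np.int16)
    col = cyc[layer % len(cyc)]
    return np.broadcast_to(col, dims).copy()


def build_academic_phantom(layout: str = "series", scale: float = 1.0
                           ) -> VoxelGrid:
    """Academic validation phantom.

    layout 'series':   lung and cortical-bone slabs transverse to the beam
    layout 'adjacent': lung (x<0) and bone (x>=0) side by side along the beam
    layout 'mixed':    background only (layer-by-layer varying HU, no
                       interfaces anywhere)

    ``scale`` multiplies the default 100 x 100 x 400 voxel counts; spacing
    stays (0.2, 0.2, 0.1) cm.
    """
    if layout not in ("series", "adjacent", "mixed"):
        raise ValueError(f"unknown layout {layout!r}")
    dims = (max(int(round(100 * scale)), 1), max(int(round(100 * scale)), 1),
            max(int(round(400 * scale)), 1))
    spacing = (0.2, 0.2, 0.1)
    origin = (-dims[0] * spacing[0] / 2.0, -dims[1] * spacing[1] / 2.0, 0.0)
    hu = _background(dims, spacing[2]).astype(np.int16)
    z = (np.arange(dims[2]) + 0.5) * spacing[2]
    if layout == "series":
        lung = (z >= SERIES_LUNG_Z[0]) & (z < SERIES_LUNG_Z[1])
        bone = (z >= SERIES_BONE_Z[0]) & (z < SERIES_BONE_Z[1])
        hu[:, :, lung] = HU_LUNG
        hu[:, :, bone] = HU_BONE
    elif layout == "adjacent":
        x = origin[0] + (np.arange(dims[0]) + 0.5) * spacing[0]
        zin = (z >= ADJACENT_Z[0]) & (z < ADJACENT_Z[1])
        left = x < 0.0
        hu[np.ix_(left, np.ones(dims[1], bool), zin)] = HU_LUNG
        hu[np.ix_(~left, np.ones(dims[1], bool), zin)] = HU_BONE
    return VoxelGrid(hu=hu, spacing=spacing, origin=origin)


def build_lateral_case(offset: float) -> tuple[VoxelGrid, BeamSpec]:
    """Half-space cortical bone (x >= 0) against lung (x < 0) with a 125 MeV
    pencil beam parallel to the interface at lateral distance ``offset`` cm
    inside the bone."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    dims = (60, 60, 130)
    spacing = (0.1, 0.2, 0.1)
    origin = (-2.0, -dims[1] * spacing[1] / 2.0, 0.0)
    if offset >= origin[0] + dims[0] * spacing[0]:
        raise ValueError("offset beyond grid")
    x = origin[0] + (np.arange(dims[0]) + 0.5) * spacing[0]
    hu = np.broadcast_to(
        np.where(x[:, None, None] < 0.0, HU_LUNG, HU_BONE).astype(np.int16),
        dims).copy()
    grid = VoxelGrid(hu=hu, spacing=spacing, origin=origin)
    beam = BeamSpec(kind="pencil", energy=125.0, entry=(offset, 0.0, 0.0),
                    direction=(0.0, 0.0, 1.0))
    return grid, beam


def build_patient_like(seed: int = 0) -> VoxelGrid:
    """Synthetic head-like phantom (stand-in for a patient CT): ellipsoidal
    soft-tissue volume with a cortical-bone shell, air cavities and teeth
    inclusions, on a 236 x 144 x 118 grid with (0.1, 0.2, 0.2) cm voxels.
    Deterministic per seed."""
    rng = np.random.default_rng(seed)
    dims = (236, 144, 118)
    spacing = (0.1, 0.2, 0.2)
    origin = (-dims[0] * spacing[0] / 2.0, -dims[1] * spacing[1] / 2.0,
              -dims[2] * spacing[2] / 2.0)
    x = origin[0] + (np.arange(dims[0]) + 0.5) * spacing[0]
    y = origin[1] + (np.arange(dims[1]) + 0.5) * spacing[1]
    z = origin[2] + (np.arange(dims[2]) + 0.5) * spacing[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    # head ellipsoid semi-axes [cm]
    ax, ay, az = 10.0, 12.0, 10.5
    r = np.sqrt((X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2)
    hu = np.full(dims, -1000, dtype=np.int16)
    soft = rng.integers(-60, 60, size=dims).astype(np.int16)
    hu[r < 1.0] = soft[r < 1.0]
    shell = (r >= 0.88) & (r < 1.0)
    hu[shell] = HU_BONE
    # air cavities (sinuses) and teeth
    for cx, cy, cz, rad, val in (
            (0.0, -6.0, 0.0, 1.6, -1000),
            (2.2, -4.0, 1.0, 1.0, -1000),
            (-2.2, -4.0, 1.0, 1.0, -1000),
            (0.0, -9.5, -2.0, 0.9, 3055),
            (1.5, -9.0, -2.0, 0.7, 3055),
            (-1.5, -9.0, -2.0, 0.7, 3055)):
        m = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 < rad ** 2
        hu[m] = val
    return VoxelGrid(hu=hu, spacing=spacing, origin=origin)
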