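"""Ray traversal, interface detection and volume I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmmc import (VoxelGrid, trace_segments, is_interface,
                  distance_to_interface, lateral_interface_distance,
                  read_volume, write_volume)
from pmmc.geometry import OutOfGridError


@pytest.fixture
def unit_grid():
    hu = np.zeros((10, 10, 10), dtype=np.int16)
    return VoxelGrid(hu=hu, spacing=(0.1, 0.1, 0.1))


def test_axis_aligned_trace(unit_grid):
    # 0.5 cm ray starting on a boundary through 0.1 cm voxels -> 5 equal cuts
    segs = trace_segments(unit_grid, [(0.05, 0.05, 0.0), (0.05, 0.05, 0.5)])
    assert len(segs) == 5
    assert all(s.cut_length == pytest.approx(0.1, abs=1e-12) for s in segs)
    assert [s.voxel_index[2] for s in segs] == [0, 1, 2, 3, 4]


def test_trace_partial_last_segment(unit_grid):
    segs = trace_segments(unit_grid, [(0.05, 0.05, 0.0), (0.05, 0.05, 0.37)])
    assert segs[-1].cut_length == pytest.approx(0.07, abs=1e-9)
    assert sum(s.cut_length for s in segs) == pytest.approx(0.37, abs=1e-9)


def test_oblique_trace_against_point_sampling(unit_grid):
    # 45-degree in-plane ray: cut lengths vs a brute-force sampling oracle
    p0 = np.array([0.02, 0.03, 0.01])
    p1 = np.array([0.82, 0.83, 0.61])
    segs = trace_segments(unit_grid, [p0, p1])
    n = 10_000
    ts = (np.arange(n) + 0.5) / n
    pts = p0 + ts[:, None] * (p1 - p0)
    idx = np.floor(pts / 0.1).astype(int)
    length = np.linalg.norm(p1 - p0)
    counts = {}
    for i, j, k in idx:
        counts[(i, j, k)] = counts.get((i, j, k), 0) + 1
    oracle = {v: c / n * length for v, c in counts.items()}
    assert set(oracle) == {s.voxel_index for s in segs}
    for s in segs:
        assert s.cut_length == pytest.approx(oracle[s.voxel_index], abs=1e-4)


def test_trace_outside_grid_portions_omitted(unit_grid):
    segs = trace_segments(unit_grid, [(-0.5, 0.05, 0.05), (1.5, 0.05, 0.05)])
    assert sum(s.cut_length for s in segs) == pytest.approx(1.0, abs=1e-9)
    assert trace_segments(unit_grid, [(5, 5, 5), (6, 6, 6)]) == []


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95),
                          st.floats(0.05, 0.95)), min_size=2, max_size=5))
def test_trace_conserves_length(points):
    hu = np.zeros((10, 10, 10), dtype=np.int16)
    grid = VoxelGrid(hu=hu, spacing=(0.1, 0.1, 0.1))
    pts = np.asarray(points)
    total = sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:]))
    segs = trace_segments(grid, pts)
    assert sum(s.cut_length for s in segs) == pytest.approx(total, abs=1e-9)


@pytest.mark.parametrize("a,b,expected", [
    (-50, 20, False),   # both inside the adipose-muscle band
    (-50, 60, True),    # band crossed at the muscle node (40)
    (40, 40, False),    # identical values
    (40, 60, False),    # shared boundary node does not separate
    (-2000, -700, False),  # clamped value shares the air-lung band
    (-2000, -500, True),   # clamped air against the lung-adipose band
])
def test_is_interface_rule(ramp, a, b, expected):
    assert is_interface(ramp, a, b) is expected
    assert is_interface(ramp, b, a) is expected  # symmetry


@settings(max_examples=100, derandomize=True)
@given(a=st.floats(-1200, 3300), b=st.floats(-1200, 3300))
def test_is_interface_symmetric(a, b):
    from pmmc import CTRamp
    ramp = CTRamp.default()
    assert is_interface(ramp, a, b) == is_interface(ramp, b, a)


def test_distance_to_interface_homogeneous(ramp, muscle_grid):
    d = distance_to_interface(muscle_grid, ramp, (0, 0, 0), (0, 0, 1), 2.0)
    assert d == pytest.approx(2.0)  # capped at max_distance
    d = distance_to_interface(muscle_grid, ramp, (0, 0, 0), (0, 0, 1), 100.0)
    assert d == pytest.approx(6.0, abs=1e-9)  # grid exit


def test_distance_to_interface_layer(ramp):
    hu = np.full((20, 20, 40), 40, dtype=np.int16)
    hu[:, :, 20:] = 1524  # cortical bone from z = 2.0 cm
    grid = VoxelGrid(hu=hu, spacing=(0.2, 0.2, 0.1), origin=(-2, -2, 0))
    d = distance_to_interface(grid, ramp, (0, 0, 0), (0, 0, 1), 10.0)
    assert d == pytest.approx(2.0, abs=1e-9)


def test_distance_to_interface_ignores_in_band_variation(ramp):
    # alternating adipose/muscle HU layers share one mixed band: no interface
    hu = np.zeros((10, 10, 40), dtype=np.int16)
    hu[:, :, ::2] = -77
    hu[:, :, 1::2] = 40
    grid = VoxelGrid(hu=hu, spacing=(0.2, 0.2, 0.1), origin=(-1, -1, 0))
    d = distance_to_interface(grid, ramp, (0, 0, 0), (0, 0, 1), 10.0)
    assert d == pytest.approx(4.0, abs=1e-9)  # grid exit, no interface found


def test_distance_to_interface_outside_raises(ramp, muscle_grid):
    with pytest.raises(OutOfGridError):
        distance_to_interface(muscle_grid, ramp, (100, 0, 0), (0, 0, 1), 1.0)


def test_lateral_interface_distance(ramp):
    # pencil ray parallel to and 0.1 cm from a bone/lung face
    hu = np.full((40, 20, 40), 1524, dtype=np.int16)
    hu[:20] = -610  # lung for x < 0
    grid = VoxelGrid(hu=hu, spacing=(0.1, 0.2, 0.1), origin=(-2, -2, 0))
    d = lateral_interface_distance(grid, ramp, (0.1, 0, 0), (0, 0, 1),
                                   step_length=2.0, radius=0.3)
    assert d == pytest.approx(0.1, abs=0.05)  # within half a voxel pitch
    # homogeneous environment returns the sentinel radius
    d = lateral_interface_distance(grid, ramp, (1.5, 0, 0), (0, 0, 1),
                                   step_length=1.0, radius=0.05)
    assert d == 0.05
    # never exceeds the radius
    for r in (0.02, 0.1, 0.5):
        d = lateral_interface_distance(grid, ramp, (0.3, 0, 0), (0, 0, 1),
                                       step_length=1.0, radius=r)
        assert d <= r + 1e-12


@pytest.mark.parametrize("suffix", [".mha", ".nrrd"])
def test_volume_roundtrip(tmp_path, suffix):
    rng = np.random.default_rng(0)
    hu = rng.integers(-1000, 3000, size=(6, 7, 8)).astype(np.int16)
    grid = VoxelGrid(hu=hu, spacing=(0.1, 0.2, 0.3), origin=(-1, 0, 2))
    path = tmp_path / f"vol{suffix}"
    write_volume(path, grid)
    back = read_volume(path)
    assert np.array_equal(back.hu, hu)
    assert back.spacing == pytest.approx(grid.spacing)
    assert back.origin == pytest.approx(grid.origin)


def test_voxel_grid_invariants():
    with pytest.raises(ValueError):
        VoxelGrid(hu=np.zeros((2, 2), dtype=np.int16), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        VoxelGrid(hu=np.zeros((2, 2, 2), dtype=np.int16), spacing=(0, 1, 1))
    g = VoxelGrid(hu=np.zeros((2, 2, 2), dtype=np.int16), spacing=(1, 1, 1))
    assert g.contains_point((0, 0, 0)) and not g.contains_point((2, 0, 0))
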