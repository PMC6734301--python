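"""Macro Monte Carlo global transport.

A proton is propagated through the voxel grid in *macro steps*: raytracing
finds the distance ``d`` to the next material interface (and the distance to
any lateral interface within 0.5 mm), a slab size is chosen from the
database, the step outcome (energy loss dE, exit position x_out, exit
direction u_out, hard-interaction flag) is sampled from the pre-simulated
histograms, the in-slab trajectory is approximated by a *hinge step* — a
straight leg along the entry direction for 30% of the slab size followed by
a straight leg to the sampled exit point — and dE is distributed over the
crossed voxels with the stopping power approximation (SPA): a linear
stopping-power profile along the track weighted by local rho*mSPR.  Below
the database threshold energy the remaining energy is deposited along the
current direction via the continuous slowing down approximation (CSDA).

The hot loop lives in :mod:`pmmc._kernels`; this module provides the typed
API plus the vectorized run driver used for full simulations.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels as K
from .database import SlabDatabase, DbTables, pack_tables
from .geometry import VoxelGrid, TrackSegment, OutOfGridError
from .materials import CTRamp
from .presim import N_BINS_ANGLE, N_BINS_DISP, _history_seeds


@dataclass
class ProtonState:
    """Phase space of one proton at the start of a macro step."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    energy: float
    weight: float = 1.0
    kind: str = "primary"  # primary | secondary_proton | neutron

    def __post_init__(self) -> None:
        u = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(u)
        if abs(n - 1.0) > 1e-6:
            u = u / n
        self.direction = tuple(u)
        if self.energy < 0:
            raise ValueError("energy must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class SpaContext:
    """Intermediate quantities of one SPA deposition."""

    mean_stopping: float    # MeV/cm, dE / d_track
    track_length: float     # cm
    gradient: float         # MeV/cm^2, linear stopping-power slope
    s0: float               # MeV/cm, stopping power at track start (clamped)
    mean_density: float     # g/cm^3, cut-length-weighted
    mean_mspr: float


@dataclass
class TransportConfig:
    """Tunables of the adaptive macro-step algorithm."""

    hinge_fraction: float = 0.30
    lateral_threshold: float = 0.05  # cm (0.5 mm)
    lateral_radius: float = 0.05     # cm, lateral search radius
    e_min: float = 10.0              # MeV, CSDA switch (database threshold)
    mode: str = "adaptive"           # adaptive | non_adaptive
    lateral_enabled: bool = True
    exit_azimuth_sigma: float = 0.6  # rad, angle-displacement azimuth spread
    closed_form_partial: bool = True  # closed-form dE rescale at truncations

    def __post_init__(self) -> None:
        if not (0.0 < self.hinge_fraction < 1.0):
            raise ValueError("hinge_fraction must be in (0, 1)")
        if self.lateral_radius <= 0:
            raise ValueError("lateral_radius must be > 0")
        if self.mode not in ("adaptive", "non_adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class HistoryRecord:
    """Per-history bookkeeping of one transported primary."""

    deposited: float
    escaped: float
    macro_steps: int

    @property
    def total(self) -> float:
        return self.deposited + self.escaped


# ---------------------------------------------------------------------------
# elementary operations (thin wrappers over the compiled kernels)
# ---------------------------------------------------------------------------

def hinge_track(x_init, u_init, x_out, slab: float,
                hinge_fraction: float = 0.30) -> np.ndarray:
    """Two-segment hinge polyline [x_init, hinge, x_out]; the hinge sits at
    ``hinge_fraction`` of the slab size along the initial direction."""
    x_init = np.asarray(x_init, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    u = np.asarray(u_init, dtype=float)
    u = u / np.linalg.norm(u)
    if np.allclose(x_out, x_init):
        raise ValueError("x_out must differ from x_init")
    hinge = x_init + hinge_fraction * slab * u
    return np.vstack([x_init, hinge, x_out])


def spa_gradient(mean_stopping: float, mean_density: float, mean_mspr: float,
                 energy: float, delta_e: float) -> float:
    """Semi-empirical linear stopping-power slope along the track [MeV/cm^2]:

        0.8 * (S_hat^2 - 4 (rho_hat*mSPR_hat)^2) / (E - dE/2)
    """
    denom = energy - 0.5 * delta_e
    if denom <= 0:
        raise ValueError("E - dE/2 must be > 0 (guarded by the e_min gate)")
    rm = mean_density * mean_mspr
    return 0.8 * (mean_stopping ** 2 - 4.0 * rm * rm) / denom


def _seg_arrays(track: Sequence[TrackSegment], grid: VoxelGrid, ramp: CTRamp):
    ny, nz = grid.dims[1], grid.dims[2]
    vox = np.array([(s.voxel_index[0] * ny + s.voxel_index[1]) * nz
                    + s.voxel_index[2] for s in track], dtype=np.int64)
    lens = np.array([s.cut_length for s in track])
    hu = grid.hu_float()
    rm = np.array([
        K.ramp_interp(hu[s.voxel_index], ramp.hu_nodes, ramp.densities)
        * K.ramp_interp(hu[s.voxel_index], ramp.hu_nodes, ramp.msprs)
        for s in track])
    return vox, lens, rm


def deposit_spa(track: Sequence[TrackSegment], delta_e: float, energy: float,
                ramp: CTRamp, grid: VoxelGrid, dose_grid: np.ndarray
                ) -> SpaContext:
    """Distribute ``delta_e`` over the track segments into ``dose_grid``
    (a per-voxel energy array shaped like the grid); returns the SPA context.

    Deposits are renormalized by a single factor so they sum to dE exactly.
    """
    if delta_e < 0:
        raise ValueError("delta_e must be >= 0")
    nvox = int(np.prod(grid.dims))
    flat = dose_grid.reshape(nvox)
    if not track:
        raise ValueError("track must be non-empty")
    vox, lens, rm = _seg_arrays(track, grid, ramp)
    dtr = float(lens.sum())
    if dtr <= 1e-12:
        flat[vox[0]] += delta_e
        return SpaContext(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    shat = delta_e / dtr
    rmhat = float((lens * rm).sum()) / dtr
    grad = spa_gradient(shat, rmhat, 1.0, energy, delta_e)
    s00 = shat - 0.5 * dtr * grad
    if s00 < 0.0:
        s00, grad = 0.0, 2.0 * shat / dtr
    elif s00 + dtr * grad < 0.0:
        s00, grad = 2.0 * shat, -2.0 * shat / dtr
    ends = s00 + np.concatenate([[0.0], np.cumsum(lens)]) * grad
    ei = lens * 0.5 * (ends[:-1] + ends[1:]) * rm / rmhat
    ei = np.maximum(ei, 0.0)
    tot = float(ei.sum())
    if tot <= 0.0:
        ei = lens * rm
        tot = float(ei.sum())
    ei *= delta_e / tot
    np.add.at(flat, vox, ei)
    # rho_hat and mSPR_hat are reported separately via the weighted product
    mean_rho = rmhat  # rho*mSPR folded; density/mSPR split is not needed downstream
    return SpaContext(mean_stopping=shat, track_length=dtr, gradient=grad,
                      s0=s00, mean_density=mean_rho, mean_mspr=1.0)


def deposit_csda(state: ProtonState, ramp: CTRamp, grid: VoxelGrid,
                 dose_grid: np.ndarray) -> float:
    """CSDA deposit of the full remaining energy along the current direction.

    Returns the energy escaping through the grid boundary (0 when the range
    ends inside); everything else is added to ``dose_grid``.
    """
    nvox = int(np.prod(grid.dims))
    cur = np.zeros(nvox)
    stamp = np.full(nvox, -1, dtype=np.int64)
    touched = np.empty(nvox, dtype=np.int64)
    hsum = np.zeros(nvox)
    p = np.asarray(state.position, dtype=float)
    u = np.asarray(state.direction, dtype=float)
    cnt, escaped = K.csda_deposit_k(
        grid.hu_float(), ramp.hu_nodes, ramp.densities, ramp.msprs,
        ramp.a_csdas, *grid.origin, *grid.spacing,
        p[0], p[1], p[2], u[0], u[1], u[2], float(state.energy),
        cur, stamp, touched, 0, 0, hsum)
    flat = dose_grid.reshape(nvox)
    for t in range(cnt):
        flat[touched[t]] += cur[touched[t]]
    flat += hsum
    return float(escaped)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of a transport run: energy deposits plus statistics.

    ``edep``      per-voxel deposited energy [MeV]
    ``edep_sq``   per-voxel sum of squared per-history deposits
    ``batch``     per-batch deposit sums (10 batches)
    ``deposited`` / ``escaped``  per-history ledgers [MeV]
    ``macro_steps`` per-history macro (or micro) step counts
    """

    edep: np.ndarray
    edep_sq: np.ndarray
    batch: np.ndarray
    deposited: np.ndarray
    escaped: np.ndarray
    macro_steps: np.ndarray
    n_histories: int
    runtime_s: float
    e0: float

    @property
    def mean_macro_steps(self) -> float:
        return float(self.macro_steps.mean())


def _sample_beam(beam, n: int, rng: np.random.Generator):
    entry = np.asarray(beam.entry, dtype=float)
    u = np.asarray(beam.direction, dtype=float)
    u = u / np.linalg.norm(u)
    entries = np.tile(entry, (n, 1))
    if beam.kind == "broad":
        wx, wy = beam.field_size
        from .database import _perp_basis
        e1, e2 = _perp_basis(u)
        offs = rng.uniform(-0.5, 0.5, size=(n, 2)) * np.array([wx, wy])
        entries = entries + offs[:, :1] * e1 + offs[:, 1:] * e2
    dirs = np.tile(u, (n, 1))
    return entries, dirs


def _alloc_accum(nvox: int, nbatch: int = 10):
    return (np.zeros(nvox), np.full(nvox, -1, dtype=np.int64),
            np.empty(min(nvox, 200_000), dtype=np.int64),
            np.zeros(nvox), np.zeros(nvox), np.zeros((nbatch, nvox)))


def run_pmmc(grid: VoxelGrid, ramp: CTRamp, db: SlabDatabase, beam,
             n_histories: int, seed: int,
             config: TransportConfig | None = None,
             tables: DbTables | None = None) -> RunResult:
    """Transport ``n_histories`` primaries of ``beam`` with the macro MC."""
    cfg = config or TransportConfig(e_min=db.e_min)
    tb = tables if tables is not None else pack_tables(db)
    rng = np.random.default_rng(seed)
    entries, dirs = _sample_beam(beam, n_histories, rng)
    seeds = _history_seeds(seed, n_histories)
    nvox = int(np.prod(grid.dims))
    cur, stamp, touched, hsum, hsumsq, batch = _alloc_accum(nvox)
    dep = np.empty(n_histories)
    esc = np.empty(n_histories)
    steps = np.empty(n_histories, dtype=np.int64)
    pcfg = db.config
    t0 = time.perf_counter()
    K.run_pmmc_k(grid.hu_float(), ramp.hu_nodes, ramp.densities, ramp.msprs,
                 ramp.a_csdas, ramp.scatter_ratios, *grid.origin, *grid.spacing,
                 entries, dirs, float(beam.energy), seeds,
                 tb.avail, tb.tvals, tb.evals,
                 tb.de_cdf, tb.de_lo, tb.de_hi, tb.de_mean,
                 tb.ex_cdf, tb.th_hi, tb.disp_hi,
                 N_BINS_ANGLE, N_BINS_DISP,
                 tb.p_el, tb.p_inel, tb.dep_cdf,
                 float(cfg.e_min),
                 pcfg.highland_constant, pcfg.x0_water,
                 pcfg.nuclear_macroscopic_xs, pcfg.elastic_macroscopic_xs,
                 pcfg.nuclear_threshold,
                 pcfg.neutron_fraction, pcfg.secondary_angle_sigma,
                 pcfg.elastic_angle_mev, pcfg.recoil_fraction,
                 cfg.hinge_fraction, cfg.lateral_threshold, cfg.lateral_radius,
                 cfg.exit_azimuth_sigma,
                 cfg.mode == "non_adaptive",
                 cfg.lateral_enabled and cfg.lateral_threshold > 0,
                 cfg.closed_form_partial,
                 cur, stamp, touched, hsum, hsumsq, batch,
                 dep, esc, steps)
    dt = time.perf_counter() - t0
    shape = grid.dims
    return RunResult(edep=hsum.reshape(shape), edep_sq=hsumsq.reshape(shape),
                     batch=batch.reshape((batch.shape[0],) + shape),
                     deposited=dep, escaped=esc, macro_steps=steps,
                     n_histories=n_histories, runtime_s=dt,
                     e0=float(beam.energy))


def transport_primary(state: ProtonState, grid: VoxelGrid, ramp: CTRamp,
                      db: SlabDatabase, config: TransportConfig,
                      dose_grid: np.ndarray, rng,
                      tables: DbTables | None = None) -> HistoryRecord:
    """Transport a single primary; deposits are added to ``dose_grid``
    (per-voxel energy, shaped like the grid)."""
    if not grid.contains_point(state.position):
        raise OutOfGridError(f"state at {state.position} outside grid")
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:
        seed = int(rng.integers(0, 2**31 - 1))

    class _Beam:
        kind = "pencil"
        entry = state.position
        direction = state.direction
        energy = state.energy
        field_size = None

    res = run_pmmc(grid, ramp, db, _Beam, 1, seed, config, tables=tables)
    dose_grid += res.edep
    return HistoryRecord(deposited=float(res.deposited[0]),
                         escaped=float(res.escaped[0]),
                         macro_steps=int(res.macro_steps[0]))
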