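"""Full condensed-history Monte Carlo on the voxel grid.

This is the package's benchmark engine: it micro-steps every proton through
the voxels with the *same* compiled physics kernels used by the slab
pre-simulator (energy loss + straggling, Highland scattering, simplified
elastic/inelastic nuclear model), so any difference between its dose and the
macro-step transport isolates the macro-step approximation itself.
Statistical uncertainty is intended to be estimated by the batch method
(10 batches by default), mirroring how an external full-MC benchmark would
be treated; the history-by-history accumulators are filled as well.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import VoxelGrid, OutOfGridError
from .materials import CTRamp
from .presim import CondensedStepConfig, _history_seeds
from .transport import ProtonState, HistoryRecord, RunResult, _sample_beam, _alloc_accum

# kernel-sharing guarantee: these symbols are the single implementation used
# by both the pre-simulator and this engine (asserted by the test suite)
SHARED_KERNELS = (K.sample_energy_loss, K.sample_deflection, K.sigma_inelastic,
                  K.sigma_elastic, K.sample_elastic, K.sample_inelastic_split,
                  K.highland_sigma_k)


@dataclass
class ReferenceConfig:
    """Micro-step settings of the reference engine; the physics constants are
    the shared :class:`CondensedStepConfig` (identical to the database's)."""

    micro_step: float = 0.01
    physics: CondensedStepConfig = field(default_factory=CondensedStepConfig)

    def __post_init__(self) -> None:
        if self.micro_step <= 0:
            raise ValueError("micro_step must be > 0")

    def effective_micro_step(self, grid: VoxelGrid) -> float:
        # cap at half the smallest voxel pitch to bound midpoint-binning error
        return min(self.micro_step, 0.5 * min(grid.spacing))


def run_reference(grid: VoxelGrid, ramp: CTRamp, beam, n_histories: int,
                  seed: int, config: ReferenceConfig | None = None) -> RunResult:
    """Micro-step transport of ``n_histories`` primaries of ``beam``."""
    cfg = config or ReferenceConfig()
    p = cfg.physics
    rng = np.random.default_rng(seed)
    entries, dirs = _sample_beam(beam, n_histories, rng)
    seeds = _history_seeds(seed, n_histories)
    nvox = int(np.prod(grid.dims))
    cur, stamp, touched, hsum, hsumsq, batch = _alloc_accum(nvox)
    dep = np.empty(n_histories)
    esc = np.empty(n_histories)
    steps = np.empty(n_histories, dtype=np.int64)
    t0 = time.perf_counter()
    K.run_reference_k(grid.hu_float(), ramp.hu_nodes, ramp.densities,
                      ramp.msprs, ramp.a_csdas, ramp.scatter_ratios,
                      *grid.origin, *grid.spacing,
                      entries, dirs, float(beam.energy), seeds,
                      cfg.effective_micro_step(grid),
                      p.straggling_coefficient, p.highland_constant,
                      p.x0_water, p.nuclear_macroscopic_xs,
                      p.elastic_macroscopic_xs, p.nuclear_threshold,
                      p.stop_energy, p.neutron_fraction,
                      p.secondary_angle_sigma, p.elastic_angle_mev,
                      p.recoil_fraction,
                      cur, stamp, touched, hsum, hsumsq, batch,
                      dep, esc, steps)
    dt = time.perf_counter() - t0
    shape = grid.dims
    return RunResult(edep=hsum.reshape(shape), edep_sq=hsumsq.reshape(shape),
                     batch=batch.reshape((batch.shape[0],) + shape),
                     deposited=dep, escaped=esc, macro_steps=steps,
                     n_histories=n_histories, runtime_s=dt,
                     e0=float(beam.energy))


def transport_full(state: ProtonState, grid: VoxelGrid, ramp: CTRamp,
                   config: ReferenceConfig, dose_grid: np.ndarray,
                   rng) -> HistoryRecord:
    """Transport a single primary with the reference engine; deposits are
    added to ``dose_grid`` (per-voxel energy, shaped like the grid)."""
    if not grid.contains_point(state.position):
        raise OutOfGridError(f"state at {state.position} outside grid")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else \
        int(rng.integers(0, 2**31 - 1))

    class _Beam:
        kind = "pencil"
        entry = state.position
        direction = state.direction
        energy = state.energy
        field_size = None

    res = run_reference(grid, ramp, _Beam, 1, seed, config)
    dose_grid += res.edep
    return HistoryRecord(deposited=float(res.deposited[0]),
                         escaped=float(res.escaped[0]),
                         macro_steps=int(res.macro_steps[0]))
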