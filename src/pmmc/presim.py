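"""Local pre-simulation: condensed-history proton transport through
homogeneous slabs, producing the macro-step parameter histograms stored in
the slab database.

Per micro step the engine applies the closed-form mean energy loss of the
analytic range model, Gaussian (Bohr-like) energy-loss straggling, a Highland
multiple-Coulomb-scattering deflection, and a simplified nuclear interaction
model (exponential attenuation split into elastic and inelastic channels).
The same compiled kernels drive the full reference MC on voxel grids, so the
database and the benchmark share micro-physics by construction.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels as K
from .materials import MaterialLike

PROTON_MASS = K.PROTON_MASS


@dataclass(frozen=True)
class CondensedStepConfig:
    """Shared micro-physics constants of the condensed-history engines.

    micro_step              cm, condensed-history step length
    highland_constant       MeV, Highland formula prefactor
    x0_water                g/cm^2, water radiation length used for scaling
    straggling_coefficient  MeV^2 cm^2/g, Bohr straggling (0.157*(Z/A) ~ 0.087)
    nuclear_threshold       MeV, nuclear channels switch off below this energy
    nuclear_macroscopic_xs  1/cm at unit density, inelastic channel (>=100 MeV)
    elastic_macroscopic_xs  1/cm at unit density, elastic channel
    elastic_angle_mev       MeV, elastic deflection scale (sigma = value/pv)
    recoil_fraction         fraction of energy deposited locally per elastic hit
    neutron_fraction        inelastic energy fraction escaping as neutrons
    secondary_angle_sigma   rad, angular spread of inelastic secondary protons
    stop_energy             MeV, protons below this deposit locally
    """

    micro_step: float = 0.01
    highland_constant: float = 14.1
    x0_water: float = 36.08
    straggling_coefficient: float = 0.087
    nuclear_threshold: float = 8.0
    nuclear_macroscopic_xs: float = 0.012
    elastic_macroscopic_xs: float = 0.006
    elastic_angle_mev: float = 30.0
    recoil_fraction: float = 0.02
    neutron_fraction: float = 0.20
    secondary_angle_sigma: float = 0.35
    stop_energy: float = 2.0

    def __post_init__(self) -> None:
        if self.micro_step <= 0:
            raise ValueError("micro_step must be > 0")
        for name in ("highland_constant", "x0_water", "straggling_coefficient",
                     "nuclear_threshold", "stop_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()


# histogram binning of the stored distributions
N_BINS_DE = 64
N_BINS_ANGLE = 32
N_BINS_DISP = 32
N_BINS_DEPTH = 32


@dataclass
class SlabRecord:
    """Macro-step parameter histograms for one (material, energy, thickness)."""

    material_name: str
    incident_energy: float
    thickness: float
    # 1-D energy-loss histogram (probabilities summing to 1) on uniform bins
    h_energy_loss: np.ndarray
    de_edges: np.ndarray
    # joint (polar exit angle, lateral displacement) histogram
    h_exit: np.ndarray
    angle_edges: np.ndarray
    disp_edges: np.ndarray
    p_elastic: float
    p_inelastic: float
    h_process_depth: np.ndarray
    depth_edges: np.ndarray
    secondary_model: dict = field(default_factory=dict)
    n_histories: int = 0
    stopped_fraction: float = 0.0

    def validate(self) -> None:
        for h in (self.h_energy_loss, self.h_exit, self.h_process_depth):
            s = float(np.sum(h))
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"histogram not normalized (sum={s})")
        if not (0.0 <= self.p_elastic and 0.0 <= self.p_inelastic
                and self.p_elastic + self.p_inelastic <= 1.0 + 1e-12):
            raise ValueError("invalid interaction probabilities")
        if self.de_edges[-1] > self.incident_energy + 1e-9:
            raise ValueError("energy-loss histogram exceeds incident energy")
        if self.disp_edges[-1] > self.thickness + 1e-9:
            raise ValueError("displacement histogram exceeds slab thickness")


def highland_angle_sigma(energy: float, path: float, material: MaterialLike,
                         config: CondensedStepConfig | None = None) -> float:
    """Highland multiple-scattering sigma [rad] for ``path`` cm of material."""
    if energy <= 0 or path <= 0:
        raise ValueError("energy and path must be > 0")
    cfg = config or CondensedStepConfig()
    rho_sc = material.density * getattr(material, "scatter_ratio", 1.0)
    return K.highland_sigma_k(energy, path, rho_sc,
                              cfg.highland_constant, cfg.x0_water)


def _history_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-history seed substreams below 2^31."""
    h = (np.uint64(seed) * np.uint64(2654435761)
         + np.arange(n, dtype=np.uint64) * np.uint64(40503))
    return ((h ^ (h >> np.uint64(16))) % np.uint64(2**31 - 1)).astype(np.int64)


def simulate_slab(material: MaterialLike, thickness: float, energy: float,
                  n_histories: int, seed: int,
                  config: CondensedStepConfig | None = None) -> SlabRecord:
    """Pre-simulate one homogeneous slab and histogram the macro-step data."""
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    if energy <= 0:
        raise ValueError("energy must be > 0")
    if n_histories < 1000:
        raise ValueError("need at least 1000 histories per slab record")
    cfg = config or CondensedStepConfig()
    micro = min(cfg.micro_step, thickness / 4.0)

    seeds = _history_seeds(seed, n_histories)
    de = np.empty(n_histories)
    th = np.empty(n_histories)
    disp = np.empty(n_histories)
    stopped = np.zeros(n_histories, dtype=np.uint8)
    depth_el = np.zeros(N_BINS_DEPTH)
    depth_inel = np.zeros(N_BINS_DEPTH)

    rho_sc = material.density * getattr(material, "scatter_ratio", 1.0)
    K.simulate_slab_k(material.a_csda, material.density, rho_sc,
                      thickness, energy, seeds, micro,
                      cfg.straggling_coefficient, cfg.highland_constant,
                      cfg.x0_water, cfg.nuclear_macroscopic_xs,
                      cfg.elastic_macroscopic_xs, cfg.nuclear_threshold,
                      cfg.stop_energy,
                      de, th, disp, stopped, depth_el, depth_inel)

    de_hi = min(float(de.max()) * (1.0 + 1e-9) + 1e-12, energy)
    de_lo = max(float(de.min()) - 1e-12, 0.0)
    if de_hi <= de_lo:
        de_hi = de_lo + 1e-9
    h_de, de_edges = np.histogram(np.clip(de, de_lo, de_hi), bins=N_BINS_DE,
                                  range=(de_lo, de_hi))

    th_hi = max(float(th.max()) * (1.0 + 1e-9), 1e-6)
    dp_hi = min(max(float(disp.max()) * (1.0 + 1e-9), 1e-6), thickness)
    h_exit, a_edges, d_edges = np.histogram2d(
        th, np.clip(disp, 0.0, dp_hi), bins=(N_BINS_ANGLE, N_BINS_DISP),
        range=((0.0, th_hi), (0.0, dp_hi)))

    p_el = float(depth_el.sum()) / n_histories
    p_inel = float(depth_inel.sum()) / n_histories
    d_tot = depth_el + depth_inel
    if d_tot.sum() > 0:
        h_depth = d_tot / d_tot.sum()
    else:
        h_depth = np.full(N_BINS_DEPTH, 1.0 / N_BINS_DEPTH)
    depth_edges = np.linspace(0.0, thickness, N_BINS_DEPTH + 1)

    rec = SlabRecord(
        material_name=getattr(material, "name", "custom"),
        incident_energy=energy,
        thickness=thickness,
        h_energy_loss=h_de / h_de.sum(),
        de_edges=de_edges,
        h_exit=h_exit / h_exit.sum(),
        angle_edges=a_edges,
        disp_edges=d_edges,
        p_elastic=p_el,
        p_inelastic=p_inel,
        h_process_depth=h_depth,
        depth_edges=depth_edges,
        secondary_model={
            "secondary_proton_fraction": 0.55,
            "neutron_fraction": cfg.neutron_fraction,
            "local_fraction": 1.0 - 0.55 - cfg.neutron_fraction,
        },
        n_histories=n_histories,
        stopped_fraction=float(stopped.mean()),
    )
    rec.validate()
    return rec
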