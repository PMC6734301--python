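"""Slab database: build, store (HDF5), load and sample macro-step parameters.

The database holds one :class:`~pmmc.presim.SlabRecord` per (ramp node
material, energy grid point, slab thickness).  A slab thickness is *available*
for a proton energy when it does not exceed 60% of the residual CSDA range —
this keeps the exit-energy spread of a macro step within the validity of the
stored histograms.  The smallest slab size is always recorded for every
(material, energy) pair so that the transport always has a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import h5py
import numpy as np

from . import _kernels as K
from .materials import CTRamp, MixedMaterial, csda_range
from .presim import (CondensedStepConfig, SlabRecord, simulate_slab,
                     N_BINS_DE, N_BINS_ANGLE, N_BINS_DISP, N_BINS_DEPTH)

DEFAULT_ENERGY_GRID = tuple(float(e) for e in range(10, 251, 10))
DEFAULT_SLAB_SIZES = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
AVAILABILITY_RANGE_FRACTION = 0.6


class DatabaseLookupError(KeyError):
    """A (material, energy, thickness) record is missing from the database."""


@dataclass
class SlabDatabase:
    ramp: CTRamp
    energy_grid: np.ndarray
    slab_sizes: np.ndarray
    records: dict = field(default_factory=dict)  # (name, E, t) -> SlabRecord
    config: CondensedStepConfig = field(default_factory=CondensedStepConfig)

    @property
    def materials(self) -> list[str]:
        return [m.name for m in self.ramp.nodes]

    @property
    def e_min(self) -> float:
        return float(self.energy_grid[0])

    def record(self, material: str, energy: float, thickness: float) -> SlabRecord:
        key = (material, float(energy), float(thickness))
        try:
            return self.records[key]
        except KeyError as err:
            raise DatabaseLookupError(key) from err

    def nearest_energy(self, energy: float) -> float:
        return float(self.energy_grid[np.argmin(np.abs(self.energy_grid - energy))])

    def available_slabs(self, mix: MixedMaterial | str, energy: float,
                        node_name: str | None = None) -> np.ndarray:
        """Slab sizes recorded at the nearest grid energy and permitted by the
        energy-availability rule for the actual material/energy."""
        if node_name is None:
            node_name = mix if isinstance(mix, str) else mix.lower_node.name
        a = (self.ramp.nodes[self.ramp.material_index(node_name)].a_csda
             if isinstance(mix, str) else mix.a_csda)
        eg = self.nearest_energy(energy)
        rmax = AVAILABILITY_RANGE_FRACTION * a * energy * (energy + 2.0)
        out = [t for t in self.slab_sizes
               if (node_name, eg, float(t)) in self.records and t <= rmax]
        return np.array(out)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config_hash"] = self.config.hash()
            f.attrs["config_json"] = _config_json(self.config)
            f.attrs["energy_grid"] = self.energy_grid
            f.attrs["slab_sizes"] = self.slab_sizes
            f.attrs["e_min"] = self.e_min
            rg = f.create_group("ramp")
            rg.attrs["names"] = [m.name for m in self.ramp.nodes]
            rg.create_dataset("hu", data=self.ramp.hu_nodes)
            rg.create_dataset("density", data=self.ramp.densities)
            rg.create_dataset("mspr", data=self.ramp.msprs)
            rg.create_dataset("a_csda", data=self.ramp.a_csdas)
            rg.create_dataset("scatter_ratio", data=self.ramp.scatter_ratios)
            for (name, e, t), rec in sorted(self.records.items()):
                g = f.create_group(f"material/{name}/E{e:g}/t{t * 10:g}")
                g.attrs["p_elastic"] = rec.p_elastic
                g.attrs["p_inelastic"] = rec.p_inelastic
                g.attrs["n_histories"] = rec.n_histories
                g.attrs["stopped_fraction"] = rec.stopped_fraction
                g.attrs["incident_energy"] = rec.incident_energy
                g.attrs["thickness"] = rec.thickness
                for k, v in rec.secondary_model.items():
                    g.attrs[f"secondary_{k}"] = v
                g.create_dataset("h_energy_loss", data=rec.h_energy_loss)
                g.create_dataset("de_edges", data=rec.de_edges)
                g.create_dataset("h_exit", data=rec.h_exit)
                g.create_dataset("angle_edges", data=rec.angle_edges)
                g.create_dataset("disp_edges", data=rec.disp_edges)
                g.create_dataset("h_process_depth", data=rec.h_process_depth)
                g.create_dataset("depth_edges", data=rec.depth_edges)

    @classmethod
    def load(cls, path, config: CondensedStepConfig | None = None) -> "SlabDatabase":
        from .materials import Material

        with h5py.File(path, "r") as f:
            rg = f["ramp"]
            names = [n if isinstance(n, str) else n.decode()
                     for n in rg.attrs["names"]]
            sc = rg["scatter_ratio"][:] if "scatter_ratio" in rg else \
                np.ones(len(names))
            ramp = CTRamp([Material(nm, *vals) for nm, *vals in zip(
                names, rg["hu"][:], rg["density"][:], rg["mspr"][:],
                rg["a_csda"][:], sc)])
            cfg = config or CondensedStepConfig()
            stored_hash = f.attrs["config_hash"]
            if stored_hash != cfg.hash():
                warnings.warn(
                    "slab database was built with a different physics config "
                    f"(hash {stored_hash} != {cfg.hash()})", stacklevel=2)
            db = cls(ramp=ramp,
                     energy_grid=np.array(f.attrs["energy_grid"]),
                     slab_sizes=np.array(f.attrs["slab_sizes"]),
                     config=cfg)
            for name in f["material"]:
                for eg in f[f"material/{name}"]:
                    for tg in f[f"material/{name}/{eg}"]:
                        g = f[f"material/{name}/{eg}/{tg}"]
                        rec = SlabRecord(
                            material_name=name,
                            incident_energy=float(g.attrs["incident_energy"]),
                            thickness=float(g.attrs["thickness"]),
                            h_energy_loss=g["h_energy_loss"][:],
                            de_edges=g["de_edges"][:],
                            h_exit=g["h_exit"][:],
                            angle_edges=g["angle_edges"][:],
                            disp_edges=g["disp_edges"][:],
                            p_elastic=float(g.attrs["p_elastic"]),
                            p_inelastic=float(g.attrs["p_inelastic"]),
                            h_process_depth=g["h_process_depth"][:],
                            depth_edges=g["depth_edges"][:],
                            n_histories=int(g.attrs["n_histories"]),
                            stopped_fraction=float(g.attrs["stopped_fraction"]),
                        )
                        db.records[(name, rec.incident_energy, rec.thickness)] = rec
        return db


def _config_json(cfg: CondensedStepConfig) -> str:
    import json
    from dataclasses import asdict
    return json.dumps(asdict(cfg), sort_keys=True)


def build_database(ramp: CTRamp,
                   config: CondensedStepConfig | None = None,
                   energy_grid=DEFAULT_ENERGY_GRID,
                   slab_sizes=DEFAULT_SLAB_SIZES,
                   n_per_record: int = 10_000,
                   seed: int = 0,
                   path=None,
                   progress=None) -> SlabDatabase:
    """Pre-simulate every available (material, energy, thickness) triple.

    A slab is simulated when ``t <= 0.6 * R_CSDA(material, E)``; the smallest
    slab size is simulated unconditionally so every (material, energy) pair
    has at least one record.
    """
    cfg = config or CondensedStepConfig()
    egrid = np.asarray(sorted(energy_grid), dtype=float)
    tvals = np.asarray(sorted(slab_sizes), dtype=float)
    if egrid.size == 0 or tvals.size == 0:
        raise ValueError("energy and slab grids must be non-empty")
    db = SlabDatabase(ramp=ramp, energy_grid=egrid, slab_sizes=tvals, config=cfg)
    total = len(ramp.nodes) * egrid.size
    done = 0
    for mi, mat in enumerate(ramp.nodes):
        for ei, e in enumerate(egrid):
            rmax = AVAILABILITY_RANGE_FRACTION * csda_range(mat, e)
            for ti, t in enumerate(tvals):
                if t > rmax and ti != 0:
                    continue
                rec_seed = (seed * 1_000_003 + mi * 10_007 + ei * 101 + ti) % (2**31 - 1)
                rec = simulate_slab(mat, float(t), float(e), n_per_record,
                                    rec_seed, cfg)
                db.records[(mat.name, float(e), float(t))] = rec
            done += 1
            if progress is not None:
                progress(done, total)
    if path is not None:
        db.save(path)
    return db


def choose_slab(db: SlabDatabase, material: MixedMaterial, energy: float,
                d: float, lateral_distance: float,
                lateral_threshold: float) -> float:
    """Adaptive slab-size choice.

    Below the lateral threshold the smallest available slab is forced;
    otherwise the available slab closest to the raytraced distance ``d`` is
    chosen (ties toward the smaller slab).
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    for node_name in (material.lower_node.name, material.upper_node.name):
        avail = db.available_slabs(material, energy, node_name=node_name)
        if avail.size:
            break
    if not avail.size:
        # fall back to the smallest recorded slab for this material
        eg = db.nearest_energy(energy)
        recorded = [t for t in db.slab_sizes
                    if (material.lower_node.name, eg, float(t)) in db.records]
        if not recorded:
            raise DatabaseLookupError((material.lower_node.name, eg))
        return float(min(recorded))
    if lateral_distance < lateral_threshold:
        return float(avail[0])
    k = int(np.argmin(np.abs(avail - d)))  # argmin takes the first (smaller) tie
    return float(avail[k])


@dataclass(frozen=True)
class MacroStepSample:
    """One sampled macro-step outcome."""

    delta_e: float
    exit_position: tuple[float, float, float]
    exit_direction: tuple[float, float, float]
    process: str  # none | elastic | inelastic
    process_point: tuple[float, float, float] | None
    slab_used: float


class DbTables(NamedTuple):
    """Database packed into flat arrays for the compiled transport kernel."""

    avail: np.ndarray       # uint8 [M, NE, NT]
    tvals: np.ndarray       # [NT]
    evals: np.ndarray       # [NE]
    de_cdf: np.ndarray      # [M, NE, NT, NB+1]
    de_lo: np.ndarray
    de_hi: np.ndarray
    de_mean: np.ndarray     # [M, NE, NT] histogram mean of dE
    ex_cdf: np.ndarray      # [M, NE, NT, NA*ND+1]
    th_hi: np.ndarray
    disp_hi: np.ndarray
    p_el: np.ndarray
    p_inel: np.ndarray
    dep_cdf: np.ndarray     # [M, NE, NT, NDEP+1]


def pack_tables(db: SlabDatabase) -> DbTables:
    M = len(db.ramp.nodes)
    NE = db.energy_grid.size
    NT = db.slab_sizes.size
    avail = np.zeros((M, NE, NT), dtype=np.uint8)
    de_cdf = np.zeros((M, NE, NT, N_BINS_DE + 1))
    de_lo = np.zeros((M, NE, NT))
    de_hi = np.zeros((M, NE, NT))
    de_mean = np.zeros((M, NE, NT))
    ex_cdf = np.zeros((M, NE, NT, N_BINS_ANGLE * N_BINS_DISP + 1))
    th_hi = np.zeros((M, NE, NT))
    disp_hi = np.zeros((M, NE, NT))
    p_el = np.zeros((M, NE, NT))
    p_inel = np.zeros((M, NE, NT))
    dep_cdf = np.zeros((M, NE, NT, N_BINS_DEPTH + 1))
    for (name, e, t), rec in db.records.items():
        m = db.ramp.material_index(name)
        ei = int(np.argmin(np.abs(db.energy_grid - e)))
        ti = int(np.argmin(np.abs(db.slab_sizes - t)))
        avail[m, ei, ti] = 1
        de_cdf[m, ei, ti, 1:] = np.cumsum(rec.h_energy_loss)
        de_cdf[m, ei, ti, -1] = 1.0
        de_lo[m, ei, ti] = rec.de_edges[0]
        de_hi[m, ei, ti] = rec.de_edges[-1]
        centers = 0.5 * (rec.de_edges[:-1] + rec.de_edges[1:])
        de_mean[m, ei, ti] = float((rec.h_energy_loss * centers).sum())
        ex_cdf[m, ei, ti, 1:] = np.cumsum(rec.h_exit.ravel())
        ex_cdf[m, ei, ti, -1] = 1.0
        th_hi[m, ei, ti] = rec.angle_edges[-1]
        disp_hi[m, ei, ti] = rec.disp_edges[-1]
        p_el[m, ei, ti] = rec.p_elastic
        p_inel[m, ei, ti] = rec.p_inelastic
        dep_cdf[m, ei, ti, 1:] = np.cumsum(rec.h_process_depth)
        dep_cdf[m, ei, ti, -1] = 1.0
    return DbTables(avail, np.asarray(db.slab_sizes, dtype=float),
                    np.asarray(db.energy_grid, dtype=float),
                    de_cdf, de_lo, de_hi, de_mean, ex_cdf, th_hi, disp_hi,
                    p_el, p_inel, dep_cdf)


def sample_macro_step(db: SlabDatabase, material: MixedMaterial, energy: float,
                      slab: float, entry, direction, rng: np.random.Generator
                      ) -> MacroStepSample:
    """Sample (dE, exit position/direction, hard process) for one macro step.

    Mixed materials are handled stochastically: the record of the lower or
    upper bracketing node is drawn with probability equal to the mix weight,
    and dE is rescaled by the closed-form CSDA loss ratio of the mixed
    material at the actual energy versus the node at the grid energy.
    """
    entry = np.asarray(entry, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    node = (material.upper_node if rng.random() < material.weight
            else material.lower_node)
    eg = db.nearest_energy(energy)
    rec = db.record(node.name, eg, float(slab))

    # dE from the histogram, uniform within the chosen bin
    p = rec.h_energy_loss
    k = rng.choice(p.size, p=p / p.sum())
    de = rng.uniform(rec.de_edges[k], rec.de_edges[k + 1])
    num = energy - K.residual_energy_k(material.a_csda,
                                       K.csda_range_k(material.a_csda, energy) - slab)
    den = eg - K.residual_energy_k(node.a_csda,
                                   K.csda_range_k(node.a_csda, eg) - slab)
    # mean-shift (not scale) to the actual material/energy: keeps the
    # straggling width of the record, which is energy-independent
    centers = 0.5 * (rec.de_edges[:-1] + rec.de_edges[1:])
    mean_rec = float((rec.h_energy_loss * centers).sum())
    if den > 1e-9:
        de += mean_rec * (num / den - 1.0)
    de = float(np.clip(de, 0.0, energy))

    # joint (angle, displacement)
    pj = rec.h_exit.ravel()
    kj = rng.choice(pj.size, p=pj / pj.sum())
    ia, idp = divmod(kj, rec.h_exit.shape[1])
    th = rng.uniform(rec.angle_edges[ia], rec.angle_edges[ia + 1])
    dsp = rng.uniform(rec.disp_edges[idp], rec.disp_edges[idp + 1])
    # pv ratio at mid-slab residual energies (matches the transport kernel)
    em_node = max(K.residual_energy_k(
        node.a_csda, K.csda_range_k(node.a_csda, eg) - 0.5 * slab), 0.5)
    em_mix = max(K.residual_energy_k(
        material.a_csda, K.csda_range_k(material.a_csda, energy) - 0.5 * slab), 0.5)
    scale = (np.sqrt((material.density * material.scatter_ratio)
                     / (node.density * node.scatter_ratio))
             * K.momentum_velocity(em_node) / K.momentum_velocity(em_mix))
    th = min(th * scale, 1.4)
    dsp = min(dsp * scale, 0.9 * slab)

    phi = rng.uniform(0.0, 2.0 * np.pi)
    e1, e2 = _perp_basis(u)
    lat = np.cos(phi) * e1 + np.sin(phi) * e2
    x_out = entry + slab * u + dsp * lat
    dphi = rng.normal(0.0, 0.6)
    u_out = np.array(K.rotate_direction(u[0], u[1], u[2], th, phi + dphi))

    process = "none"
    x_proc = None
    r = rng.random()
    if r < rec.p_inelastic:
        process = "inelastic"
    elif r < rec.p_inelastic + rec.p_elastic:
        process = "elastic"
    if process != "none":
        pd = rec.h_process_depth
        kd = rng.choice(pd.size, p=pd / pd.sum())
        depth = rng.uniform(rec.depth_edges[kd], rec.depth_edges[kd + 1])
        x_proc = tuple(entry + depth * u)
    return MacroStepSample(delta_e=de, exit_position=tuple(x_out),
                           exit_direction=tuple(u_out), process=process,
                           process_point=x_proc, slab_used=float(slab))


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if abs(u[2]) < 0.9:
        e1 = np.array([u[1], -u[0], 0.0])
    else:
        e1 = np.array([0.0, u[2], -u[1]])
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)
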