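"""Scoring and validation: dose grids, integrated depth dose, gamma index,
statistical uncertainty and the efficiency metric.

Dose is reported as energy per unit mass (MeV/g) on the HU grid.  The gamma
index combines a global dose-difference criterion (percent of the reference
maximum) with a distance-to-agreement criterion; a point passes when
gamma <= 1.  For depth-dose curves a 1-D gamma with sub-voxel interpolation
of the test curve is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VoxelGrid
from .materials import CTRamp

_AXES = {"x": 0, "y": 1, "z": 2}


class EmptyRoiError(ValueError):
    """No evaluation points remain above the dose cutoff."""


@dataclass
class DoseGrid:
    """Dose volume co-registered with an HU grid.

    ``dose`` is MeV/g per history-normalized run; ``variance`` is the
    per-voxel variance estimate of ``dose`` (same units squared).
    """

    geometry: VoxelGrid
    dose: np.ndarray
    variance: np.ndarray | None = None
    n_histories: int = 0

    def __post_init__(self) -> None:
        if self.dose.shape != self.geometry.dims:
            raise ValueError("dose shape must match the HU grid")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")


@dataclass
class GammaResult:
    gamma_map: np.ndarray
    pass_rate: float  # percent of evaluated points with gamma <= 1
    dd_criterion: float  # percent, global
    dta_criterion: float  # cm
    cutoff: float  # fraction of the reference maximum
    evaluated: np.ndarray | None = None  # mask of evaluated points


@dataclass
class EfficiencyReport:
    time: float  # s
    mean_rel_variance: float  # sigma^2 (relative) over the ROI
    efficiency: float  # 1 / (T * sigma^2)
    mean_macro_steps_per_history: float


def voxel_mass(grid: VoxelGrid, ramp: CTRamp) -> np.ndarray:
    """Per-voxel mass [g] from the HU-interpolated density."""
    rho = np.interp(grid.hu_float(), ramp.hu_nodes, ramp.densities)
    return rho * grid.voxel_volume()


def dose_from_run(run, grid: VoxelGrid, ramp: CTRamp) -> DoseGrid:
    """Convert a transport RunResult (energy per voxel) to dose per history.

    The history-by-history variance of the mean is computed from the
    sum/sum-of-squares accumulators.
    """
    mass = voxel_mass(grid, ramp)
    n = run.n_histories
    mean_e = run.edep / n
    var_e = (run.edep_sq / n - mean_e ** 2) / max(n - 1, 1)
    return DoseGrid(geometry=grid, dose=mean_e / mass,
                    variance=np.maximum(var_e, 0.0) / mass ** 2,
                    n_histories=n)


def integrated_depth_dose(dose: DoseGrid, beam_axis: str = "z",
                          ramp: CTRamp | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Energy deposited per transverse slice as a function of depth.

    Sums dose * voxel mass over each slice perpendicular to the beam axis;
    when ``ramp`` is omitted the dose grid is assumed to already hold energy
    per voxel... it is required for a dose (MeV/g) grid.
    """
    if beam_axis not in _AXES:
        raise ValueError(f"unsupported beam axis {beam_axis!r} (use x, y or z)")
    ax = _AXES[beam_axis]
    g = dose.geometry
    if ramp is not None:
        energy = dose.dose * voxel_mass(g, ramp)
    else:
        energy = dose.dose
    other = tuple(i for i in range(3) if i != ax)
    idd = energy.sum(axis=other)
    depths = (np.arange(g.dims[ax]) + 0.5) * g.spacing[ax] + g.origin[ax]
    return depths, idd


def idd_max_difference(depths: np.ndarray, ref: np.ndarray, test: np.ndarray,
                       dta_cm: float = 0.0) -> float:
    """Maximum |test - ref| as percent of the reference curve maximum.

    With ``dta_cm`` > 0 each reference point receives distance-to-agreement
    credit: the difference is taken against the closest test value within
    +-dta (finely interpolated), which discounts sub-resolution offsets of
    steep gradients.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    rmax = ref.max()
    if rmax <= 0:
        raise ValueError("reference curve is empty")
    if dta_cm <= 0:
        return float(np.abs(test - ref).max() / rmax * 100.0)
    from scipy.interpolate import CubicSpline
    fine = np.linspace(depths[0], depths[-1], depths.size * 20)
    tfine = CubicSpline(depths, test)(fine)
    worst = 0.0
    for d, r in zip(depths, ref):
        m = np.abs(fine - d) <= dta_cm
        diff = np.abs(tfine[m] - r).min()
        worst = max(worst, diff)
    return float(worst / rmax * 100.0)


def gamma_1d(x: np.ndarray, ref: np.ndarray, test: np.ndarray,
             dd_percent: float, dta_cm: float,
             cutoff_fraction: float = 0.0) -> GammaResult:
    """1-D gamma of two curves on a common axis (global normalization)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    rmax = float(ref.max())
    if rmax <= 0:
        raise EmptyRoiError("reference curve is empty")
    dd_abs = dd_percent / 100.0 * rmax
    from scipy.interpolate import CubicSpline
    fine = np.linspace(x[0], x[-1], max(x.size * 20, 2000))
    # cubic sub-voxel interpolation: linear interpolation cannot reach a
    # peaked maximum between sample points, which biases the comparison
    tfine = CubicSpline(x, test)(fine)
    gam = np.empty_like(ref)
    for i, (xi, ri) in enumerate(zip(x, ref)):
        m = np.abs(fine - xi) <= 3.0 * dta_cm
        if not np.any(m):
            m = np.array([np.argmin(np.abs(fine - xi))])
        g2 = ((fine[m] - xi) / dta_cm) ** 2 + ((tfine[m] - ri) / dd_abs) ** 2
        gam[i] = np.sqrt(g2.min())
    mask = ref >= cutoff_fraction * rmax
    if not np.any(mask):
        raise EmptyRoiError("no points above the dose cutoff")
    pass_rate = float(100.0 * np.mean(gam[mask] <= 1.0))
    return GammaResult(gamma_map=gam, pass_rate=pass_rate,
                       dd_criterion=dd_percent, dta_criterion=dta_cm,
                       cutoff=cutoff_fraction, evaluated=mask)


def gamma_evaluate(reference: DoseGrid, test: DoseGrid, dd_percent: float,
                   dta_cm: float, cutoff_fraction: float = 0.2,
                   dims: int = 3, beam_axis: str = "z",
                   ramp: CTRamp | None = None) -> GammaResult:
    """Gamma evaluation between two co-registered dose grids.

    ``dims=1`` compares integrated depth dose curves along ``beam_axis``;
    ``dims=3`` searches a refined lattice (factor 3 per axis) within a
    3*dta radius around each evaluated voxel, interpolating the test dose.
    """
    if dd_percent <= 0 or dta_cm <= 0:
        raise ValueError("dd and dta must be > 0")
    if reference.geometry.dims != test.geometry.dims:
        raise ValueError("grids are not co-registered")
    if dims == 1:
        depths, r = integrated_depth_dose(reference, beam_axis, ramp)
        _, t = integrated_depth_dose(test, beam_axis, ramp)
        return gamma_1d(depths, r, t, dd_percent, dta_cm, cutoff_fraction)
    if dims != 3:
        raise ValueError("dims must be 1 or 3")

    from scipy.ndimage import map_coordinates

    g = reference.geometry
    ref = reference.dose
    tst = test.dose
    rmax = float(ref.max())
    if rmax <= 0:
        raise EmptyRoiError("reference dose is empty")
    dd_abs = dd_percent / 100.0 * rmax
    sp = np.asarray(g.spacing)

    # candidate offsets on a 3x-refined lattice within a 3*dta sphere
    steps = [np.arange(-int(3 * dta_cm / (s / 3)), int(3 * dta_cm / (s / 3)) + 1)
             * (s / 3) for s in sp]
    ox, oy, oz = np.meshgrid(*steps, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    offs = offs[np.linalg.norm(offs, axis=1) <= 3.0 * dta_cm]

    mask = ref >= cutoff_fraction * rmax
    if not np.any(mask):
        raise EmptyRoiError("no voxels above the dose cutoff")
    pts = np.argwhere(mask).astype(float)  # voxel indices of evaluated points
    best = np.full(pts.shape[0], np.inf)
    for off in offs:
        coords = (pts + off / sp).T
        tval = map_coordinates(tst, coords, order=1, mode="nearest")
        g2 = (np.linalg.norm(off) / dta_cm) ** 2 + \
            ((tval - ref[mask]) / dd_abs) ** 2
        best = np.minimum(best, g2)
    gam = np.zeros_like(ref)
    gam[mask] = np.sqrt(best)
    pass_rate = float(100.0 * np.mean(gam[mask] <= 1.0))
    return GammaResult(gamma_map=gam, pass_rate=pass_rate,
                       dd_criterion=dd_percent, dta_criterion=dta_cm,
                       cutoff=cutoff_fraction, evaluated=mask)


def gamma_brute_force(reference: DoseGrid, test: DoseGrid, dd_percent: float,
                      dta_cm: float, cutoff_fraction: float = 0.2
                      ) -> GammaResult:
    """Exhaustive voxel-center gamma search (no interpolation); the slow
    independent oracle for :func:`gamma_evaluate`."""
    g = reference.geometry
    ref = reference.dose
    tst = test.dose
    rmax = float(ref.max())
    dd_abs = dd_percent / 100.0 * rmax
    sp = np.asarray(g.spacing)
    coords = [np.arange(n) * s for n, s in zip(g.dims, sp)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    pos = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tflat = tst.ravel()
    mask = ref >= cutoff_fraction * rmax
    gam = np.zeros_like(ref)
    for idx in np.argwhere(mask):
        p = idx * sp
        d2 = ((pos - p) ** 2).sum(axis=1)
        g2 = d2 / dta_cm ** 2 + ((tflat - ref[tuple(idx)]) / dd_abs) ** 2
        gam[tuple(idx)] = np.sqrt(g2.min())
    pass_rate = float(100.0 * np.mean(gam[mask] <= 1.0))
    return GammaResult(gamma_map=gam, pass_rate=pass_rate,
                       dd_criterion=dd_percent, dta_criterion=dta_cm,
                       cutoff=cutoff_fraction, evaluated=mask)


def uncertainty(run=None, method: str = "history_by_history",
                edep=None, edep_sq=None, batch=None, n_histories=None,
                roi_fraction: float = 0.5):
    """Per-voxel standard deviation of the mean deposit plus an ROI summary.

    ``method='history_by_history'`` uses the sum / sum-of-squares
    accumulators; ``method='batch'`` the variance of batch means.  The ROI
    summary is the mean relative sigma over voxels above ``roi_fraction`` of
    the maximum.
    Returns (sigma_per_voxel, mean_relative_sigma_in_roi).
    """
    if run is not None:
        edep, edep_sq, batch = run.edep, run.edep_sq, run.batch
        n_histories = run.n_histories
    if method == "history_by_history":
        n = n_histories
        if n is None or n < 2:
            raise ValueError("need at least 2 histories")
        mean = edep / n
        var = np.maximum(edep_sq / n - mean ** 2, 0.0) / (n - 1)
        sigma = np.sqrt(var)
    elif method == "batch":
        if batch is None or batch.shape[0] < 2:
            raise ValueError("need at least 2 batches")
        nb = batch.shape[0]
        # per-batch means on the per-history scale; their spread estimates
        # the variance of the overall per-history mean
        bmeans = batch / (n_histories / nb)
        sigma = np.sqrt(np.maximum(bmeans.var(axis=0, ddof=1), 0.0) / nb)
    else:
        raise ValueError(f"unknown method {method!r}")
    mean = edep / n_histories
    mmax = mean.max()
    roi = mean > roi_fraction * mmax
    if not np.any(roi):
        raise ValueError("empty ROI")
    rel = sigma[roi] / mean[roi]
    return sigma, float(rel.mean())


def efficiency(time_s: float, sigma_roi: float,
               mean_macro_steps: float = 0.0) -> EfficiencyReport:
    """Efficiency  epsilon = 1 / (T * sigma^2)  plus the hardware-independent
    mean-macro-steps-per-history proxy."""
    if time_s <= 0 or sigma_roi <= 0:
        raise ValueError("time and sigma must be > 0")
    return EfficiencyReport(time=time_s, mean_rel_variance=sigma_roi ** 2,
                            efficiency=1.0 / (time_s * sigma_roi ** 2),
                            mean_macro_steps_per_history=mean_macro_steps)


def efficiency_ratio(a: EfficiencyReport, b: EfficiencyReport) -> float:
    """epsilon_a / epsilon_b = (T_b sigma_b^2) / (T_a sigma_a^2)."""
    return a.efficiency / b.efficiency


def isodose_contours(dose: DoseGrid, slice_axis: str = "y", index: int | None = None,
                     levels=(0.1, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)):
    """Isodose lines (fractions of the slice maximum) of one plane, as lists
    of (level, contour polyline in cm) — a reporting convenience."""
    from skimage import measure

    ax = _AXES[slice_axis]
    if index is None:
        index = dose.geometry.dims[ax] // 2
    sl = [slice(None)] * 3
    sl[ax] = index
    plane = dose.dose[tuple(sl)]
    sp = [s for i, s in enumerate(dose.geometry.spacing) if i != ax]
    out = []
    dmax = plane.max()
    for lv in levels:
        for c in measure.find_contours(plane, lv * dmax):
            out.append((lv, c * np.asarray(sp)))
    return out
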