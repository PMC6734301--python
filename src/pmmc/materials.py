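"""CT calibration ramp and the analytic proton stopping-power model.

A CT ramp maps Hounsfield units (HU) to material properties via a small set
of node materials (air ... teeth).  HU values between two nodes define a
*mixed material* whose density, mass stopping power ratio (mSPR) and CSDA
coefficient are linear interpolations of the bracketing nodes.

The whole package uses one consistent analytic range/stopping-power model:

    R_CSDA(E) = a_csda * E * (E + 2 MeV)          [cm]
    S(E)      = dE/dR = 1 / (a_csda * (2E + 2))   [MeV/cm]
    E(R)      = -1 + sqrt(1 + R / a_csda)         [MeV]

so that range, stopping power and residual energy are exact closed-form
inverses of each other.  ``a_csda`` is a material-dependent fit coefficient
(cm/MeV^2) to tabulated proton range data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence, Union

import numpy as np
import yaml


@dataclass(frozen=True)
class Material:
    """One node of the CT ramp."""

    name: str
    hu_node: float
    density: float  # g/cm^3
    mspr: float  # mass stopping power ratio to water
    a_csda: float  # cm/MeV^2
    scatter_ratio: float = 1.0  # X0(water)/X0(material), per g/cm^2

    def __post_init__(self) -> None:
        if self.density <= 0 or self.mspr <= 0 or self.a_csda <= 0:
            raise ValueError(f"material {self.name!r}: density, mspr and a_csda must be > 0")
        if self.scatter_ratio <= 0:
            raise ValueError(f"material {self.name!r}: scatter_ratio must be > 0")


@dataclass(frozen=True)
class MixedMaterial:
    """Interpolated material at an HU value between two ramp nodes."""

    lower_node: Material
    upper_node: Material
    weight: float  # fraction in [0, 1] toward the upper node
    density: float
    mspr: float
    a_csda: float
    scatter_ratio: float = 1.0

    @property
    def name(self) -> str:
        return f"{self.lower_node.name}/{self.upper_node.name}@{self.weight:.3f}"


MaterialLike = Union[Material, MixedMaterial]


class CTRamp:
    """Ordered list of node materials with strictly increasing HU values.

    Lookup at any HU is continuous and piecewise linear between nodes and
    clamps to the end nodes outside the ramp range.
    """

    def __init__(self, nodes: Sequence[Material]):
        if len(nodes) < 2:
            raise ValueError("a CT ramp needs at least 2 node materials")
        hu = [m.hu_node for m in nodes]
        if any(b <= a for a, b in zip(hu, hu[1:])):
            raise ValueError("ramp HU nodes must be strictly increasing")
        self.nodes: tuple[Material, ...] = tuple(nodes)
        # flat arrays consumed by the compiled kernels
        self.hu_nodes = np.array(hu, dtype=np.float64)
        self.densities = np.array([m.density for m in nodes], dtype=np.float64)
        self.msprs = np.array([m.mspr for m in nodes], dtype=np.float64)
        self.a_csdas = np.array([m.a_csda for m in nodes], dtype=np.float64)
        self.scatter_ratios = np.array([m.scatter_ratio for m in nodes],
                                       dtype=np.float64)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dicts(cls, rows: Sequence[dict]) -> "CTRamp":
        return cls([
            Material(r["name"], float(r["hu"]), float(r["density"]),
                     float(r["mspr"]), float(r["a_csda"]),
                     float(r.get("scatter_ratio", 1.0)))
            for r in rows
        ])

    @classmethod
    def from_yaml(cls, path) -> "CTRamp":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dicts(doc["materials"])

    @classmethod
    def default(cls) -> "CTRamp":
        """The ramp shipped with the package (7 standard tissue nodes)."""
        text = resources.files("pmmc.data").joinpath("ct_ramp.yaml").read_text()
        return cls.from_dicts(yaml.safe_load(text)["materials"])

    # -- lookup -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def material_index(self, name: str) -> int:
        for i, m in enumerate(self.nodes):
            if m.name == name:
                return i
        raise KeyError(name)

    def band_index(self, hu: float) -> int:
        """Index ``b`` such that hu lies in [node_b, node_{b+1}] (clamped)."""
        i = int(np.searchsorted(self.hu_nodes, hu, side="right")) - 1
        return min(max(i, 0), len(self.nodes) - 2)

    def hu_to_mix(self, hu: float) -> MixedMaterial:
        return hu_to_mix(self, hu)


def hu_to_mix(ramp: CTRamp, hu: float) -> MixedMaterial:
    """Interpolate the ramp at ``hu`` (clamped outside the ramp range)."""
    b = ramp.band_index(hu)
    lo, up = ramp.nodes[b], ramp.nodes[b + 1]
    hu_c = min(max(hu, lo.hu_node), up.hu_node)
    w = (hu_c - lo.hu_node) / (up.hu_node - lo.hu_node)
    return MixedMaterial(
        lower_node=lo,
        upper_node=up,
        weight=w,
        density=lo.density + w * (up.density - lo.density),
        mspr=lo.mspr + w * (up.mspr - lo.mspr),
        a_csda=lo.a_csda + w * (up.a_csda - lo.a_csda),
        scatter_ratio=lo.scatter_ratio + w * (up.scatter_ratio - lo.scatter_ratio),
    )


def _a_of(mix: Union[MaterialLike, float]) -> float:
    if isinstance(mix, (int, float)):
        return float(mix)
    return mix.a_csda


def csda_range(mix: Union[MaterialLike, float], energy: float) -> float:
    """CSDA range [cm] at kinetic energy [MeV]: a_csda * E * (E + 2)."""
    if energy < 0:
        raise ValueError("energy must be >= 0")
    return _a_of(mix) * energy * (energy + 2.0)


def stopping_power(mix: Union[MaterialLike, float], energy: float) -> float:
    """Linear stopping power [MeV/cm]; analytic inverse-derivative of the range fit."""
    if energy <= 0:
        raise ValueError("energy must be > 0")
    return 1.0 / (_a_of(mix) * (2.0 * energy + 2.0))


def residual_energy(mix: Union[MaterialLike, float], range_left: float) -> float:
    """Kinetic energy [MeV] whose CSDA range equals ``range_left`` [cm]."""
    if range_left < 0:
        raise ValueError("range_left must be >= 0")
    return -1.0 + math.sqrt(1.0 + range_left / _a_of(mix))
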