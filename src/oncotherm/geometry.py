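"""Simulation domain, vascular zoning, and treatment-protocol configuration.

The tumor is modeled as a sphere embedded in a shell of normal tissue.  By
microvessel density the tumor is split into three concentric zones — a poorly
vascularized hypoxic core, a quiescent middle band, and a well-perfused
proliferative rim — with functional lymphatics present only in the normal
shell.  The default working geometry is 1-D spherically symmetric, which is
sufficient for the radially interpretable drug-delivery results; the focused
ultrasound stage uses its own small axisymmetric grid (see
:mod:`oncotherm.hifu`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Zone",
    "TissueDomain",
    "ZoneMap",
    "ProtocolConfig",
    "Protocol",
    "Agent",
    "build_domain",
    "dose_to_plasma_concentration",
    "DOSE_TO_PLASMA_FACTOR",
]

#: Calibrated linear mapping from body-surface dose (mg/m^2) to injected
#: systemic plasma concentration (kg/m^3): 50 mg/m^2 -> 0.0191 kg/m^3.
DOSE_TO_PLASMA_FACTOR = 0.0191 / 50.0  # = 3.82e-4 kg m^-3 per mg m^-2


class Zone(enum.IntEnum):
    """Tissue zones ordered by increasing microvascular density."""

    HYPOXIC = 0
    QUIESCENT = 1
    PROLIFERATIVE = 2
    NORMAL = 3


class Protocol(str, enum.Enum):
    CLASSICAL_CHEMO = "classical_chemo"
    THERMOCHEMO = "thermochemo"
    THERMODOX = "thermodox"
    ABLATION_THEN_MEDICATION = "ablation_then_medication"
    MEDICATION_THEN_ABLATION = "medication_then_ablation"


class Agent(str, enum.Enum):
    FREE_DOX = "free_dox"
    THERMODOX = "thermodox"


@dataclass(frozen=True)
class TissueDomain:
    """Discretized 1-D spherically symmetric tissue domain.

    Node ``i`` sits at radius ``i * grid_spacing``; the associated finite
    volume is the spherical shell between the half-way faces, so sums of
    ``node_volumes`` reproduce the total domain volume exactly.
    """

    tumor_radius: float = 5.0e-3  # m
    normal_shell_thickness: float = 5.0e-3  # m
    grid_spacing: float = 1.0e-4  # m
    symmetry: str = "radial_1d"

    def __post_init__(self):
        if self.tumor_radius <= 0:
            raise ValueError("tumor_radius must be positive")
        if self.normal_shell_thickness < 0:
            raise ValueError("normal_shell_thickness must be non-negative")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.symmetry not in ("radial_1d", "axisymmetric_2d"):
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        if self.symmetry == "radial_1d" and self.tumor_radius / self.grid_spacing < 50:
            raise ValueError(
                "grid_spacing too coarse: radial_1d mode requires >= 50 nodes "
                "across the tumor radius"
            )

    @property
    def outer_radius(self) -> float:
        return self.tumor_radius + self.normal_shell_thickness

    @property
    def n_nodes(self) -> int:
        return int(round(self.outer_radius / self.grid_spacing)) + 1

    @property
    def node_positions(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.grid_spacing

    @property
    def face_radii(self) -> np.ndarray:
        """Radii of the finite-volume faces between adjacent nodes."""
        r = self.node_positions
        return 0.5 * (r[:-1] + r[1:])

    @property
    def node_volumes(self) -> np.ndarray:
        r = self.node_positions
        dr = self.grid_spacing
        r_in = np.clip(r - dr / 2, 0.0, None)
        r_out = np.minimum(r + dr / 2, self.outer_radius)
        return 4.0 * np.pi / 3.0 * (r_out**3 - r_in**3)

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.node_positions <= self.tumor_radius + 1e-12

    @property
    def tumor_volume(self) -> float:
        return float(self.node_volumes[self.tumor_mask].sum())


# Per-zone physiology defaults.  Vascular surface density S/V follows the
# nominal tumor magnitude 2e4 m^-1 scaled 0.1/0.5/1.0 across
# hypoxic/quiescent/proliferative; perfusion scales identically.  Lymphatic
# drainage is zero on all tumor zones (no functional lymphatics).
_DEFAULT_SV = {Zone.HYPOXIC: 2.0e3, Zone.QUIESCENT: 1.0e4,
               Zone.PROLIFERATIVE: 2.0e4, Zone.NORMAL: 7.0e3}
_DEFAULT_PERFUSION = {Zone.HYPOXIC: 2.0e-4, Zone.QUIESCENT: 1.0e-3,
                      Zone.PROLIFERATIVE: 2.0e-3, Zone.NORMAL: 1.0e-3}
_DEFAULT_LYMPH = {Zone.HYPOXIC: 0.0, Zone.QUIESCENT: 0.0,
                  Zone.PROLIFERATIVE: 0.0, Zone.NORMAL: 5.0e-8}


@dataclass
class ZoneMap:
    """Per-node zone labels and zone-resolved vascular physiology.

    Attributes
    ----------
    zone_of_node : integer array of :class:`Zone` values per node.
    surface_area_density : vascular surface per tissue volume S/V (m^-1).
    perfusion_rate : blood perfusion (s^-1).
    lymphatic_drainage : lymphatic drainage coefficient (Pa^-1 s^-1),
        non-zero only in normal tissue.
    """

    zone_of_node: np.ndarray
    surface_area_density: np.ndarray
    perfusion_rate: np.ndarray
    lymphatic_drainage: np.ndarray

    def __post_init__(self):
        sv = {z: self.surface_area_density[self.zone_of_node == z] for z in Zone}
        means = {z: v.mean() for z, v in sv.items() if v.size}
        if all(z in means for z in (Zone.HYPOXIC, Zone.QUIESCENT, Zone.PROLIFERATIVE)):
            if not (means[Zone.HYPOXIC] < means[Zone.QUIESCENT] < means[Zone.PROLIFERATIVE]):
                raise ValueError("S/V must increase hypoxic < quiescent < proliferative")
        tumor = self.zone_of_node != Zone.NORMAL
        if np.any(self.lymphatic_drainage[tumor] != 0.0):
            raise ValueError("lymphatic drainage must vanish on tumor zones")

    def mask(self, zone: Zone) -> np.ndarray:
        return self.zone_of_node == zone


@dataclass
class ProtocolConfig:
    """One treatment run: drug, dose, and heating/ablation timeline."""

    protocol: Protocol = Protocol.CLASSICAL_CHEMO
    dose: float = 50.0  # mg/m^2
    agent: Agent = Agent.FREE_DOX
    hyperthermia_window: tuple[float, float] = (0.0, 0.0)  # (start, duration) s
    ablation_window: tuple[float, float] = (0.0, 0.0)  # (start, duration) s
    total_sim_time: float = 86400.0  # s

    def __post_init__(self):
        self.protocol = Protocol(self.protocol)
        self.agent = Agent(self.agent)
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        for name, (start, dur) in (("hyperthermia", self.hyperthermia_window),
                                   ("ablation", self.ablation_window)):
            if dur < 0 or start < 0:
                raise ValueError(f"{name} window must be non-negative")
            if start + dur > self.total_sim_time + 1e-9:
                raise ValueError(f"{name} window exceeds total_sim_time")
        if self._overlaps(self.hyperthermia_window, self.ablation_window):
            raise ValueError("hyperthermia and ablation windows overlap")
        if self.agent is Agent.THERMODOX and self.hyperthermia_window[1] <= 0:
            raise ValueError("thermodox protocols require a hyperthermia window")

    @staticmethod
    def _overlaps(w1, w2) -> bool:
        (s1, d1), (s2, d2) = w1, w2
        if d1 <= 0 or d2 <= 0:
            return False
        return max(s1, s2) < min(s1 + d1, s2 + d2)


def build_domain(
    tumor_radius: float = 5.0e-3,
    normal_shell_thickness: float = 5.0e-3,
    grid_spacing: float = 1.0e-4,
    zone_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    surface_area_density: dict | None = None,
    perfusion_rate: dict | None = None,
    lymphatic_drainage: dict | None = None,
) -> tuple[TissueDomain, ZoneMap]:
    """Build the radial tissue domain and its vascular zone map.

    ``zone_boundaries`` are the hypoxic/quiescent and quiescent/proliferative
    boundaries as fractions of the tumor radius.  Every node is assigned
    exactly one zone; nodes beyond the tumor radius are normal tissue.
    """
    domain = TissueDomain(tumor_radius, normal_shell_thickness, grid_spacing)
    b1, b2 = zone_boundaries
    if not (0.0 <= b1 <= b2 <= 1.0):
        raise ValueError("zone boundaries must satisfy 0 <= b1 <= b2 <= 1")
    r = domain.node_positions
    frac = r / tumor_radius
    zone = np.full(domain.n_nodes, int(Zone.NORMAL), dtype=np.int64)
    tumor = domain.tumor_mask
    zone[tumor] = np.int64(Zone.PROLIFERATIVE)
    zone[tumor & (frac < b2)] = np.int64(Zone.QUIESCENT)
    zone[tumor & (frac < b1)] = np.int64(Zone.HYPOXIC)

    sv_tbl = {**_DEFAULT_SV, **(surface_area_density or {})}
    pf_tbl = {**_DEFAULT_PERFUSION, **(perfusion_rate or {})}
    ly_tbl = {**_DEFAULT_LYMPH, **(lymphatic_drainage or {})}
    sv = np.array([sv_tbl[Zone(z)] for z in zone])
    pf = np.array([pf_tbl[Zone(z)] for z in zone])
    ly = np.array([ly_tbl[Zone(z)] for z in zone])
    zones = ZoneMap(zone, sv, pf, ly)
    return domain, zones


def dose_to_plasma_concentration(dose: float, agent: Agent | str = Agent.FREE_DOX) -> float:
    """Convert a body-surface dose (mg/m^2) to the injected plasma
    concentration (kg/m^3 of doxorubicin equivalents).

    Linear with the calibrated factor :data:`DOSE_TO_PLASMA_FACTOR`; the same
    mapping applies to free drug and to liposome-encapsulated drug, since
    concentrations are expressed in drug equivalents.
    """
    Agent(agent)  # validate
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return DOSE_TO_PLASMA_FACTOR * dose
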