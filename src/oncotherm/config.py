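"""YAML run-configuration loading with strict key validation.

A run file holds optional sections — geometry, zones, fluid,
thermal_response, bioheat, drug, carrier, mnp, amf, hifu, transport, pd,
protocol — whose keys map one-to-one onto the corresponding parameter
dataclasses (all SI units; see each dataclass docstring).  Unknown sections
or keys are rejected outright rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fluid import FluidParams
from .geometry import Agent, Protocol, ProtocolConfig, build_domain
from .hifu import TransducerSpec
from .hyperthermia import AMFSettings, BioheatParams, MNPProperties
from .pd import PDParams
from .pk import PKRates, PKVolumes
from .thermal import ThermalScaling
from .transport import TransportParams

__all__ = ["SimulationConfig", "load_config", "default_config"]

_GEOMETRY_KEYS = {"tumor_radius", "normal_shell_thickness", "grid_spacing",
                  "zone_boundaries"}


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


@dataclass
class SimulationConfig:
    """Fully resolved configuration for one simulation run."""

    geometry: dict = field(default_factory=dict)
    fluid: FluidParams = field(default_factory=FluidParams)
    bioheat: BioheatParams = field(default_factory=BioheatParams)
    mnp: MNPProperties = field(default_factory=MNPProperties)
    amf: AMFSettings = field(default_factory=AMFSettings)
    hifu: TransducerSpec = field(default_factory=TransducerSpec)
    pk: PKRates = field(default_factory=PKRates)
    pk_volumes: PKVolumes = field(default_factory=PKVolumes)
    transport: TransportParams = field(default_factory=TransportParams)
    pd: PDParams = field(default_factory=PDParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def build_domain(self):
        return build_domain(**self.geometry)


_SECTIONS = {
    "geometry": None,
    "fluid": FluidParams,
    "bioheat": BioheatParams,
    "mnp": MNPProperties,
    "amf": AMFSettings,
    "hifu": TransducerSpec,
    "drug": PKRates,
    "carrier": PKVolumes,
    "transport": TransportParams,
    "pd": PDParams,
    "protocol": ProtocolConfig,
    "thermal_response": None,
}


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")

    cfg = SimulationConfig()
    if "geometry" in raw:
        bad = set(raw["geometry"]) - _GEOMETRY_KEYS
        if bad:
            raise ValueError(f"unknown keys in [geometry]: {sorted(bad)}")
        geo = dict(raw["geometry"])
        if "zone_boundaries" in geo:
            geo["zone_boundaries"] = tuple(geo["zone_boundaries"])
        cfg.geometry = geo
    if "fluid" in raw:
        cfg.fluid = _build(FluidParams, raw["fluid"], "fluid")
    if "bioheat" in raw:
        cfg.bioheat = _build(BioheatParams, raw["bioheat"], "bioheat")
    if "mnp" in raw:
        cfg.mnp = _build(MNPProperties, raw["mnp"], "mnp")
    if "amf" in raw:
        cfg.amf = _build(AMFSettings, raw["amf"], "amf")
    if "hifu" in raw:
        cfg.hifu = _build(TransducerSpec, raw["hifu"], "hifu")
    if "drug" in raw:
        cfg.pk = _build(PKRates, raw["drug"], "drug")
    if "carrier" in raw:
        cfg.pk_volumes = _build(PKVolumes, raw["carrier"], "carrier")
    if "transport" in raw:
        cfg.transport = _build(TransportParams, raw["transport"], "transport")
    if "pd" in raw:
        cfg.pd = _build(PDParams, raw["pd"], "pd")
    if "protocol" in raw:
        sec = dict(raw["protocol"])
        for key in ("hyperthermia_window", "ablation_window"):
            if key in sec:
                sec[key] = tuple(sec[key])
        cfg.protocol = _build(ProtocolConfig, sec, "protocol")
    if "thermal_response" in raw:
        sec = raw["thermal_response"]
        bad = set(sec) - {"form", "transmembrane_anchor", "permeability_anchor"}
        if bad:
            raise ValueError(f"unknown keys in [thermal_response]: {sorted(bad)}")
        # anchors validated by construction
        for key in ("transmembrane_anchor", "permeability_anchor"):
            if key in sec:
                ThermalScaling(*sec[key])
    return cfg


def default_config() -> SimulationConfig:
    return SimulationConfig()
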