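"""YAML configuration: cable/synapse/integrator settings, morphometry
parameters and the feature-column alias map.

Example::

    biophysics:
      cable: {Cm: 1.0, Ri: 100.0, Rm: 20000.0, Em: -70.0}
      synapse: {tau_syn: 2.0, Esyn: 0.0, gbar_density: 132.0, onset: 0.0}
      simulation: {dt_us: 1.0, duration_ms: 50.0}
      parent_dendrite: {diameter: 3.0, length: 20.0}
      coupling: symmetric        # or child_ra
    morphometry:
      n_stations: 32
      neck_fraction: 0.7
      head_threshold: 0.43
    aliases:
      "Spine Part Volume": Volume
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mesh_morphometry import DEFAULT_HEAD_THRESHOLD_UM, DEFAULT_NECK_FRACTION
from .spine_biophysics import (
    DEFAULT_PARENT_DENDRITE,
    CableParams,
    SimulationConfig,
    SynapseParams,
)

__all__ = ["MorphometryConfig", "ToolConfig", "load_config"]


@dataclass(frozen=True)
class MorphometryConfig:
    n_stations: int = 32
    neck_fraction: float = DEFAULT_NECK_FRACTION
    head_threshold: float = DEFAULT_HEAD_THRESHOLD_UM


@dataclass
class ToolConfig:
    cable: CableParams = field(default_factory=CableParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    parent_dendrite: tuple[float, float] = DEFAULT_PARENT_DENDRITE
    coupling: str = "symmetric"
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    aliases: dict[str, str] = field(default_factory=dict)


def load_config(path=None) -> ToolConfig:
    """Build a ToolConfig from a YAML file; None gives all defaults."""
    if path is None:
        return ToolConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bio = raw.get("biophysics", {}) or {}
    morph = raw.get("morphometry", {}) or {}
    parent = bio.get("parent_dendrite", {}) or {}
    return ToolConfig(
        cable=CableParams(**(bio.get("cable", {}) or {})),
        synapse=SynapseParams(**(bio.get("synapse", {}) or {})),
        simulation=SimulationConfig(**(bio.get("simulation", {}) or {})),
        parent_dendrite=(
            float(parent.get("diameter", DEFAULT_PARENT_DENDRITE[0])),
            float(parent.get("length", DEFAULT_PARENT_DENDRITE[1])),
        ),
        coupling=bio.get("coupling", "symmetric"),
        morphometry=MorphometryConfig(**morph),
        aliases=dict(raw.get("aliases", {}) or {}),
    )
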