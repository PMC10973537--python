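"""YAML configuration for simulation and gradient parameters."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .gradients import GradientParams
from .simulate import HierarchySpec, SimulationConfig

__all__ = ["load_config", "save_config"]

_SECTIONS = {
    "simulation": SimulationConfig,
    "hierarchy": HierarchySpec,
    "gradients": GradientParams,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config with optional simulation/hierarchy/gradients blocks.

    Unknown keys raise immediately (via the dataclass constructors) rather
    than being silently dropped.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for section, cls in _SECTIONS.items():
        out[section] = cls(**raw.get(section, {}))
    return out


def save_config(
    path: str | Path,
    simulation: SimulationConfig | None = None,
    hierarchy: HierarchySpec | None = None,
    gradients: GradientParams | None = None,
) -> None:
    """Echo the effective parameters into a YAML provenance block."""
    doc = {
        "simulation": asdict(simulation or SimulationConfig()),
        "hierarchy": asdict(hierarchy or HierarchySpec()),
        "gradients": asdict(gradients or GradientParams()),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
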