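"""Structured configuration: a YAML/JSON schema with explicit units.

Every physical quantity in a scenario file is written as
``{value: <number>, unit: <string>}`` and the unit string is checked
against the one the model expects (cm, g/cm^3, cm^2/g).  Unknown keys are
rejected so typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .physics import CapsuleSpec, MaterialSpec, UnitGeometry, ValidationError
from .scenarios import ScenarioBundle, leksell4c_fixture

log = logging.getLogger(__name__)

_UNIT_ALIASES = {
    "cm": {"cm"},
    "g/cm^3": {"g/cm^3", "g/cm3", "g cm^-3"},
    "cm^2/g": {"cm^2/g", "cm2/g", "cm^2 g^-1"},
}

_RUN_KEYS = {"scheme", "epochs", "n_front", "histories", "seed",
             "capacity", "holders", "target", "ns"}


class ConfigError(ValidationError):
    """A configuration file failed validation; the message names the key."""


@dataclass
class RunConfig:
    """A validated scenario plus optional command parameters."""

    bundle: ScenarioBundle
    run: dict[str, Any] = field(default_factory=dict)
    source_path: Path | None = None


def _quantity(node: Any, key: str, unit: str, *, minimum: float | None = None,
              strict_minimum: bool = False) -> float:
    if not isinstance(node, dict) or set(node) != {"value", "unit"}:
        raise ConfigError(
            f"{key}: expected a {{value, unit}} mapping, got {node!r}")
    if node["unit"] not in _UNIT_ALIASES[unit]:
        raise ConfigError(
            f"{key}: expected unit {unit!r}, got {node['unit']!r}")
    try:
        value = float(node["value"])
    except (TypeError, ValueError):
        raise ConfigError(f"{key}: non-numeric value {node['value']!r}") from None
    if minimum is not None:
        if strict_minimum and not value > minimum:
            raise ConfigError(f"{key}: must be > {minimum}, got {value}")
        if not strict_minimum and not value >= minimum:
            raise ConfigError(f"{key}: must be >= {minimum}, got {value}")
    return value


def _check_keys(node: dict, allowed: set[str], context: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")


def _material(node: Any, key: str) -> MaterialSpec:
    if not isinstance(node, dict):
        raise ConfigError(f"{key}: expected a mapping")
    _check_keys(node, {"name", "mass_attenuation", "density"}, key)
    for req in ("mass_attenuation", "density"):
        if req not in node:
            raise ConfigError(f"{key}: missing required key {req!r}")
    return MaterialSpec(
        name=str(node.get("name", key)),
        mass_attenuation=_quantity(node["mass_attenuation"],
                                   f"{key}.mass_attenuation", "cm^2/g",
                                   minimum=0.0),
        density=_quantity(node["density"], f"{key}.density", "g/cm^3",
                          minimum=0.0, strict_minimum=True),
    )


def parse_scenario(doc: dict) -> ScenarioBundle:
    """Validate a parsed scenario mapping into a :class:`ScenarioBundle`."""
    _check_keys(doc, {"materials", "capsule", "geometry"}, "scenario")
    for req in ("materials", "capsule", "geometry"):
        if req not in doc:
            raise ConfigError(f"scenario: missing required key {req!r}")

    mats = doc["materials"]
    _check_keys(mats, {"active", "shell"}, "scenario.materials")
    for req in ("active", "shell"):
        if req not in mats:
            raise ConfigError(f"scenario.materials: missing key {req!r}")
    active = _material(mats["active"], "scenario.materials.active")
    shell = _material(mats["shell"], "scenario.materials.shell")

    cap = doc["capsule"]
    _check_keys(cap, {"active_height", "shell_front_height",
                      "shell_back_height", "capsule_pitch", "active_radius"},
                "scenario.capsule")
    for req in ("active_height", "shell_front_height", "shell_back_height"):
        if req not in cap:
            raise ConfigError(f"scenario.capsule: missing key {req!r}")
    heights = {k: _quantity(cap[k], f"scenario.capsule.{k}", "cm", minimum=0.0)
               for k in ("active_height", "shell_front_height",
                         "shell_back_height")}
    if "capsule_pitch" in cap:
        pitch = _quantity(cap["capsule_pitch"], "scenario.capsule.capsule_pitch",
                          "cm", minimum=0.0, strict_minimum=True)
    else:
        pitch = sum(heights.values())
        log.info("capsule_pitch not given; defaulting to the layer sum "
                 "%.4g cm (capsules abut with no gap)", pitch)
    radius = (_quantity(cap["active_radius"], "scenario.capsule.active_radius",
                        "cm", minimum=0.0)
              if "active_radius" in cap else 0.05)

    geo = doc["geometry"]
    _check_keys(geo, {"source_focus_distance"}, "scenario.geometry")
    if "source_focus_distance" not in geo:
        raise ConfigError("scenario.geometry: missing key "
                          "'source_focus_distance'")
    distance = _quantity(geo["source_focus_distance"],
                         "scenario.geometry.source_focus_distance", "cm",
                         minimum=0.0, strict_minimum=True)

    capsule = CapsuleSpec(active_material=active, shell_material=shell,
                          capsule_pitch=pitch, active_radius=radius, **heights)
    return ScenarioBundle(capsule=capsule,
                          geometry=UnitGeometry(source_focus_distance=distance))


def read_config(path: str | Path) -> RunConfig:
    """Read and fully validate a scenario/run configuration file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(doc, {"scenario", "run"}, str(path))
    if "scenario" not in doc:
        raise ConfigError(f"{path}: missing required key 'scenario'")
    bundle = parse_scenario(doc["scenario"])
    run = doc.get("run") or {}
    _check_keys(run, _RUN_KEYS, f"{path}:run")
    return RunConfig(bundle=bundle, run=dict(run), source_path=path)


def scenario_to_doc(bundle: ScenarioBundle) -> dict:
    """Serialize a bundle back to the schema (inverse of parse_scenario)."""

    def q(value: float, unit: str) -> dict:
        return {"value": value, "unit": unit}

    def mat(m: MaterialSpec) -> dict:
        return {"name": m.name,
                "mass_attenuation": q(m.mass_attenuation, "cm^2/g"),
                "density": q(m.density, "g/cm^3")}

    c = bundle.capsule
    return {"scenario": {
        "materials": {"active": mat(c.active_material),
                      "shell": mat(c.shell_material)},
        "capsule": {
            "active_height": q(c.active_height, "cm"),
            "shell_front_height": q(c.shell_front_height, "cm"),
            "shell_back_height": q(c.shell_back_height, "cm"),
            "capsule_pitch": q(c.capsule_pitch, "cm"),
            "active_radius": q(c.active_radius, "cm"),
        },
        "geometry": {
            "source_focus_distance": q(bundle.geometry.source_focus_distance, "cm"),
        },
    }}


def export_fixture(name: str, path: str | Path) -> Path:
    """Write a named packaged fixture as a scenario config file."""
    fixtures = {"leksell4c": leksell4c_fixture}
    if name not in fixtures:
        raise ConfigError(f"unknown fixture {name!r}; "
                          f"available: {sorted(fixtures)}")
    path = Path(path)
    doc = scenario_to_doc(fixtures[name]())
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_bundle(scenario: str | Path) -> ScenarioBundle:
    """Resolve a scenario reference: a fixture name or a config file path."""
    if str(scenario) == "leksell4c":
        return leksell4c_fixture()
    return read_config(scenario).bundle
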