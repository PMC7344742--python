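"""Run configuration: a single TOML or YAML document.

Sections ``[materials]``, ``[mechanoreg]``, ``[remodeling]``, ``[load]``,
``[geometry]``, ``[output]``; every algorithm constant is reachable here and
unknown keys are rejected (typo safety).  The fully resolved configuration
(defaults expanded) is echoed into every run directory and suffices to
reproduce the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import GeometryConfig
from .materials import TissueLibrary, TissueProperties
from .model import LoadSpec, MechanoRegParams, RemodelingParams

__all__ = ["RunConfig", "OutputConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class OutputConfig:
    write_vtk: bool = False
    vtk_every: int = 10  # record every k-th day/iteration
    log_level: str = "info"


@dataclass
class RunConfig:
    materials: TissueLibrary = field(default_factory=TissueLibrary)
    mechanoreg: MechanoRegParams = field(default_factory=MechanoRegParams)
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    load: LoadSpec = field(default_factory=LoadSpec)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    mesh_path: str | None = None  # read this mesh instead of generating
    tags_path: str | None = None

    def echo(self) -> dict:
        """Fully resolved configuration as a plain JSON-serializable dict."""
        doc: dict = {}
        for name in ("mechanoreg", "remodeling", "load", "geometry", "output"):
            doc[name] = dataclasses.asdict(getattr(self, name))
        doc["materials"] = {
            "bone_modulus_multiplier": self.materials.bone_modulus_multiplier,
            "table": {
                k: dataclasses.asdict(v) for k, v in sorted(self.materials.table.items())
            },
        }
        doc["mesh_path"] = self.mesh_path
        doc["tags_path"] = self.tags_path
        return doc

    def echo_json(self) -> str:
        return json.dumps(self.echo(), indent=1, sort_keys=True)


def _build(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] section: {exc}") from exc


def _build_materials(section: dict) -> TissueLibrary:
    section = dict(section)
    mult = section.pop("bone_modulus_multiplier", 1.0)
    table_over = section.pop("table", {})
    if section:
        raise ConfigError(f"unknown key(s) in [materials]: {sorted(section)}")
    lib = TissueLibrary(bone_modulus_multiplier=mult)
    for phen, props in table_over.items():
        if phen not in lib.table:
            raise ConfigError(f"unknown material {phen!r} in [materials.table]")
        base = dataclasses.asdict(lib.table[phen])
        unknown = set(props) - set(base)
        if unknown:
            raise ConfigError(f"unknown key(s) for material {phen!r}: {sorted(unknown)}")
        base.update(props)
        lib.table[phen] = TissueProperties(**base)
    return lib


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration (defaults when ``path`` is None).

    ``overrides`` is a nested {section: {key: value}} mapping applied on top
    (used by CLI flags such as ``--days`` or ``--bone-multiplier``).
    """
    doc: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix == ".toml":
            doc = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            doc = yaml.safe_load(path.read_text()) or {}
        else:
            raise ConfigError(f"config must be .toml or .yaml, got {path.name}")
    for sec, kv in (overrides or {}).items():
        doc.setdefault(sec, {}).update(kv)

    known = {"materials", "mechanoreg", "remodeling", "load", "geometry", "output", "mesh_path", "tags_path"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
    load_sec = dict(doc.get("load", {}))
    if "direction" in load_sec and load_sec["direction"] is not None:
        load_sec["direction"] = tuple(load_sec["direction"])
    return RunConfig(
        materials=_build_materials(doc.get("materials", {})),
        mechanoreg=_build(MechanoRegParams, doc.get("mechanoreg", {}), "mechanoreg"),
        remodeling=_build(RemodelingParams, doc.get("remodeling", {}), "remodeling"),
        load=_build(LoadSpec, load_sec, "load"),
        geometry=_build(GeometryConfig, doc.get("geometry", {}), "geometry"),
        output=_build(OutputConfig, doc.get("output", {}), "output"),
        mesh_path=doc.get("mesh_path"),
        tags_path=doc.get("tags_path"),
    )
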