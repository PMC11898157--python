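"""YAML configuration loading for generator and scanner specifications."""

from __future__ import annotations

from pathlib import Path

import yaml

from .synthetic_ct import (
    BonePhantomParams,
    Insert,
    PhantomSpec,
    ScanProtocol,
    SurgicalStageParams,
)

__all__ = [
    "load_config",
    "phantom_spec_from_dict",
    "scan_protocol_from_dict",
    "bone_params_from_dict",
    "stage_params_from_dict",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    inserts = [
        Insert(
            material=i["material"],
            density_gcc=float(i["density_gcc"]),
            radius_mm=float(i["radius_mm"]),
            height_mm=float(i["height_mm"]),
            center_mm=tuple(float(c) for c in i["center_mm"]),
        )
        for i in d["inserts"]
    ]
    return PhantomSpec(inserts=inserts, base_density_gcc=float(d.get("base_density_gcc", 1.05)))


def scan_protocol_from_dict(d: dict) -> ScanProtocol:
    return ScanProtocol(**d)


def bone_params_from_dict(d: dict) -> BonePhantomParams:
    d = dict(d)
    if "outer_radius_mm" in d and isinstance(d["outer_radius_mm"], (list, tuple)):
        d["outer_radius_mm"] = tuple(float(v) for v in d["outer_radius_mm"])
    return BonePhantomParams(**d)


def stage_params_from_dict(d: dict) -> SurgicalStageParams:
    return SurgicalStageParams(**d)
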