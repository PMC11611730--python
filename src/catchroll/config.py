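"""Flat YAML/JSON serialization of bond, geometry and simulation parameters.

One named block per mechanotype; rates in 1/s, distances nm, lengths um.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .bonds import BellTransition, BondParams, CatchBondParams, SlipBondParams
from .mechanics import ParticleGeometry

__all__ = [
    "bond_to_dict",
    "bond_from_dict",
    "save_registry",
    "load_registry",
]


def _bell_to_dict(t: BellTransition) -> dict:
    return {
        "zero_force_rate_per_s": t.zero_force_rate,
        "force_scale_distance_nm": t.force_scale_distance,
    }


def _bell_from_dict(d: dict) -> BellTransition:
    return BellTransition(
        zero_force_rate=float(d["zero_force_rate_per_s"]),
        force_scale_distance=float(d["force_scale_distance_nm"]),
    )


def bond_to_dict(p: BondParams) -> dict:
    if isinstance(p, SlipBondParams):
        return {
            "kind": "slip",
            "label": p.label,
            "on_rate_per_s": p.on_rate,
            "off": _bell_to_dict(p.off),
        }
    return {
        "kind": "catch",
        "label": p.label,
        "on_rate_per_s": p.on_rate,
        "off_weak": _bell_to_dict(p.off_weak),
        "interconvert": _bell_to_dict(p.interconvert),
        "revert": _bell_to_dict(p.revert),
        "off_strong": _bell_to_dict(p.off_strong),
    }


def bond_from_dict(d: dict) -> BondParams:
    kind = d.get("kind")
    if kind == "slip":
        return SlipBondParams(
            off=_bell_from_dict(d["off"]),
            on_rate=float(d.get("on_rate_per_s", 10.0)),
            label=d.get("label", "slip"),
        )
    if kind == "catch":
        return CatchBondParams(
            off_weak=_bell_from_dict(d["off_weak"]),
            interconvert=_bell_from_dict(d["interconvert"]),
            revert=_bell_from_dict(d["revert"]),
            off_strong=_bell_from_dict(d["off_strong"]),
            on_rate=float(d.get("on_rate_per_s", 10.0)),
            label=d.get("label", "catch"),
        )
    raise ValueError(f"unknown bond kind {kind!r}")


def save_registry(
    bonds: dict[str, BondParams],
    path: str | Path,
    geometry: ParticleGeometry | None = None,
) -> None:
    """Write a named registry of mechanotypes (plus optional geometry)."""
    doc: dict = {
        "units": {"rates": "1/s", "distances": "nm", "lengths": "um"},
        "mechanotypes": {name: bond_to_dict(p) for name, p in bonds.items()},
    }
    if geometry is not None:
        doc["geometry"] = {
            "radius_um": geometry.radius,
            "gap_height_um": geometry.gap_height,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_registry(
    path: str | Path,
) -> tuple[dict[str, BondParams], ParticleGeometry | None]:
    doc = yaml.safe_load(Path(path).read_text())
    bonds = {
        name: bond_from_dict(d) for name, d in doc.get("mechanotypes", {}).items()
    }
    geom = None
    if "geometry" in doc:
        g = doc["geometry"]
        geom = ParticleGeometry(
            radius=float(g["radius_um"]), gap_height=float(g["gap_height_um"])
        )
    return bonds, geom
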