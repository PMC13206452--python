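"""Configuration files and tidy-CSV readers/writers.

Compound configs use a flat dotted-key format (one scalar per key) so that
every parameter is grep-able and diffs stay line-per-parameter; physiology
and regimen configs are plain nested YAML.  Profile/metrics CSVs carry a
provenance header (``# key=value`` comment lines: package version, config
hash, seed) and are readable with ``pandas.read_csv(..., comment='#')``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compound import (
    ClearanceSpec,
    CompoundModel,
    InteractionEntry,
    PhysChem,
    TransporterKinetics,
)
from .physiology import PhysiologySpec
from .simulate import RegimenSpec

__all__ = [
    "compound_to_flat",
    "compound_from_flat",
    "save_compound",
    "load_compound",
    "save_physiology",
    "load_physiology",
    "save_regimen",
    "load_regimen",
    "write_table",
    "read_table",
    "config_hash",
]


class ConfigError(ValueError):
    pass


# -- compound: flat dotted keys ------------------------------------------------

def compound_to_flat(compound: CompoundModel) -> dict[str, object]:
    flat: dict[str, object] = {"name": compound.name}
    for k, v in asdict(compound.physchem).items():
        flat[f"physchem.{k}"] = v
    for k, v in asdict(compound.clearance).items():
        if v is not None:
            flat[f"clearance.{k}"] = v
    for t in compound.transporters:
        prefix = f"transporters.{t.transporter_id}"
        for k, v in asdict(t).items():
            if k != "transporter_id" and v is not None:
                flat[f"{prefix}.{k}"] = v
    for i, e in enumerate(compound.interactions):
        prefix = f"interactions.{i}"
        for k, v in asdict(e).items():
            if v is not None:
                flat[f"{prefix}.{k}"] = v
    flat["intestinal_permeability"] = compound.intestinal_permeability
    flat["organ_permeability"] = compound.organ_permeability
    return flat


def _nest(flat: dict[str, object]) -> dict:
    tree: dict = {}
    for key, value in flat.items():
        node = tree
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return tree


def compound_from_flat(flat: dict[str, object]) -> CompoundModel:
    tree = _nest(flat)
    try:
        transporters = tuple(
            TransporterKinetics(transporter_id=tid, **params)
            for tid, params in tree.get("transporters", {}).items()
        )
        interactions = tuple(
            InteractionEntry(**tree["interactions"][idx])
            for idx in sorted(tree.get("interactions", {}), key=int)
        )
        return CompoundModel(
            name=tree["name"],
            physchem=PhysChem(**tree["physchem"]),
            clearance=ClearanceSpec(**tree["clearance"]),
            transporters=transporters,
            interactions=interactions,
            intestinal_permeability=tree.get("intestinal_permeability", 0.0),
            organ_permeability=tree.get("organ_permeability", 0.0),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid compound config: {exc}") from exc


def save_compound(compound: CompoundModel, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(compound_to_flat(compound), sort_keys=True)
    )


def load_compound(path: str | Path) -> CompoundModel:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"compound config not found: {path}")
    return compound_from_flat(yaml.safe_load(path.read_text()))


# -- physiology / regimen: nested YAML ----------------------------------------

def save_physiology(physiology: PhysiologySpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(physiology), sort_keys=True))


def load_physiology(path: str | Path) -> PhysiologySpec:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"physiology config not found: {path}")
    data = yaml.safe_load(path.read_text())
    try:
        return PhysiologySpec(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid physiology config: {exc}") from exc


def save_regimen(regimen: RegimenSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(regimen), sort_keys=True))


def load_regimen(path: str | Path) -> RegimenSpec:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"regimen config not found: {path}")
    try:
        return RegimenSpec(**yaml.safe_load(path.read_text()))
    except TypeError as exc:
        raise ConfigError(f"invalid regimen config: {exc}") from exc


# -- tidy CSV with provenance header ------------------------------------------

def config_hash(*objects) -> str:
    """Stable short hash of configuration objects, for output provenance."""
    blob = json.dumps(
        [asdict(o) if hasattr(o, "__dataclass_fields__") else o for o in objects],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(
    frame: pd.DataFrame, path: str | Path, provenance: dict[str, object] | None = None
) -> None:
    path = Path(path)
    header = {"pbpkddi_version": __version__, **(provenance or {})}
    lines = [f"# {k}={v}" for k, v in header.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
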