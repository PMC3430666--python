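"""Frame tables, YAML run configuration and provenance records.

The frame-table dialect is plain CSV with header ``t,cell_id,type,x_um,
y_um`` (single-frame digitized tables may omit ``t`` and ``cell_id``).
Type labels accept the aliases red/green/r/g in any case on read and
are canonicalised to RED/GREEN on write.  Coordinates are microns with
the origin at the field centre.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adhesion import AdhesionParams
from .engine import FrameStack, SimConfig
from .mechanics import ExclusionParams, MotionParams, TYPE_CODES

_ALIASES = {"RED": "RED", "R": "RED", "GREEN": "GREEN", "G": "GREEN"}


def canonical_type(label) -> str:
    key = str(label).strip().upper()
    if key not in _ALIASES:
        raise ValueError(f"unknown type label {label!r} (expected RED/GREEN)")
    return _ALIASES[key]


def from_pixel_coords(stack: FrameStack, pixel_um: float,
                      field_radius_um: float = 500.0) -> FrameStack:
    """Convert a stack digitized in top-left-origin pixel coordinates
    (y down) to centre-origin microns (y up)."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    xy = stack.xy * pixel_um
    xy[:, :, 0] -= field_radius_um
    xy[:, :, 1] = field_radius_um - xy[:, :, 1]
    return FrameStack(stack.times, xy, stack.types, units="um")


def write_frames(stack: FrameStack, path) -> None:
    """Write a FrameStack as a long-format frame table."""
    labels = stack.type_labels()
    parts = []
    for i, t in enumerate(stack.times):
        parts.append(pd.DataFrame({
            "t": int(t) if float(t).is_integer() else float(t),
            "cell_id": np.arange(stack.n_cells),
            "type": labels,
            "x_um": stack.xy[i, :, 0],
            "y_um": stack.xy[i, :, 1],
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_frames(path) -> FrameStack:
    """Read a frame table (or single-frame digitized table) as a
    FrameStack.  Malformed rows raise with their line number."""
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"x_um", "y_um", "type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[["x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"{path}: missing coordinate at line {line}")
    types_str = df["type"].map(canonical_type)
    if "t" not in df.columns:
        codes = types_str.map(TYPE_CODES).to_numpy()
        xy = df[["x_um", "y_um"]].to_numpy()[None, :, :]
        return FrameStack(np.array([0]), xy, codes, units="um")
    times = np.sort(df["t"].unique())
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: multi-frame tables need a cell_id column")
    counts = df.groupby("t")["cell_id"].count()
    if counts.nunique() != 1:
        raise ValueError(f"{path}: cell count differs between frames")
    n = int(counts.iloc[0])
    xy = np.empty((len(times), n, 2))
    codes = None
    for i, t in enumerate(times):
        sub = df[df["t"] == t].sort_values("cell_id")
        xy[i] = sub[["x_um", "y_um"]].to_numpy()
        if codes is None:
            codes = sub["type"].map(canonical_type).map(TYPE_CODES).to_numpy()
    return FrameStack(times, xy, codes, units="um")


# --- configuration -----------------------------------------------------

_BLOCKS = {
    "motion": MotionParams,
    "exclusion": ExclusionParams,
    "adhesion": AdhesionParams,
}
_ENGINE_KEYS = {"n_cells", "red_fraction", "n_steps", "snapshot_every",
                "seed", "init_mode"}


def _build(cls, block: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    if cls is AdhesionParams and isinstance(block.get("seize"), str):
        block = dict(block)
        block["seize"] = math.inf  # literal "inf" disables strengthening
    return cls(**block)


def config_from_dict(doc: dict) -> SimConfig:
    doc = dict(doc or {})
    kwargs = {}
    for name, cls in _BLOCKS.items():
        kwargs[name] = _build(cls, doc.pop(name, {}) or {}, name)
    engine_block = doc.pop("engine", {}) or {}
    unknown = set(doc) | (set(engine_block) - _ENGINE_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(engine_block)
    return SimConfig(**kwargs)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_to_dict(config: SimConfig) -> dict:
    doc = {name: dataclasses.asdict(getattr(config, name))
           for name in _BLOCKS}
    if math.isinf(doc["adhesion"]["seize"]):
        doc["adhesion"]["seize"] = "inf"
    doc["engine"] = {k: getattr(config, k) for k in sorted(_ENGINE_KEYS)}
    return doc


def write_resolved_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_provenance(path, seed, extra: dict | None = None) -> None:
    """Machine-readable record of how an output was produced."""
    rec = {"package": "adhesim", "version": __version__, "seed": seed}
    rec.update(extra or {})
    with open(path, "w") as fh:
        json.dump(rec, fh, indent=2, default=float)
        fh.write("\n")
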