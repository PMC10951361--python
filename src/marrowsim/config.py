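"""YAML configuration round-trip for simulations.

A config file holds one section per parameter group; unknown keys are
rejected so typos fail loudly.  ``mask_path`` may point to a ``.npy`` bone
density array used instead of procedural trabecular generation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import engine as eng
from . import fields as flds
from . import myeloma as mye
from . import remodeling as rem
from . import therapy as thr
from .grid import GridSpec

_SECTIONS = {
    "grid": GridSpec,
    "engine": eng.EngineConfig,
    "field_params": flds.FieldParams,
    "remodel": rem.RemodelingParams,
    "mm": mye.MMParams,
    "schedule": thr.TherapySchedule,
    "resistance": thr.ResistanceParams,
}


def _build(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    if cls is thr.TherapySchedule and "drug" in payload:
        payload = {**payload, "drug": thr.Drug[str(payload["drug"]).upper()]}
    return cls(**payload)


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into Simulation keyword arguments."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kw[section] = _build(cls, raw.pop(section) or {})
    for scalar in ("target_bone_fraction", "tumor", "drugs_from_start", "preset", "seed"):
        if scalar in raw:
            kw[scalar] = raw.pop(scalar)
    if "mask_path" in raw:
        kw["mask"] = np.load(raw.pop("mask_path"))
    if raw:
        raise ValueError(f"unknown config sections: {sorted(raw)}")
    return kw


def dump_config(kw: dict, path: str | Path) -> None:
    """Write Simulation keyword arguments back to YAML (config echo)."""
    out: dict = {}
    for section in _SECTIONS:
        if section in kw and kw[section] is not None:
            d = dataclasses.asdict(kw[section])
            if "drug" in d and isinstance(d["drug"], thr.Drug):
                d["drug"] = d["drug"].value
            out[section] = d
    for scalar in ("target_bone_fraction", "tumor", "drugs_from_start", "preset", "seed"):
        if scalar in kw:
            out[scalar] = kw[scalar]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
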