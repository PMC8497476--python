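"""Device JSON files, phase-diagram CSV, and structured reports.

Device spec file format (JSON object; all lengths in μm, surface
tension in mN/m, viscosity in mPa·s — converted to SI exactly on load):

    {
      "name": "basic",
      "rails": [
        {"id": "HR1", "kind": "HIGH", "height": 300, "width": 1000,
         "length": 5000, "lane_id": "lane1",
         "footprint": [[x, y], ...]}            # optional, μm
      ],
      "ports": [
        {"id": "P_asp", "diameter": 600, "lane_id": "lane1",
         "role": "ASPIRATION"}
      ],
      "lr_footprint": [[x, y], ...],            # μm vertices
      "fluids": {"myfluid": {"surface_tension": 57.0,
                             "receding_contact_angle_deg": 0,
                             "viscosity": 11.6}}  # optional inline
    }

Schema checks collect every failure at once; unknown keys are rejected.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path
from typing import Union

import pandas as pd

from .exceptions import DeviceParseError
from .geometry import DeviceSpec, Fluid, Port, PortRole, RailKind, RailSegment
from .units import m_to_um, mn_per_m_to_n_per_m, n_per_m_to_mn_per_m, um_to_m

__all__ = [
    "device_to_dict",
    "device_from_dict",
    "load_device",
    "save_device",
    "load_inline_fluids",
    "write_phase_diagram_csv",
    "report",
]

_RAIL_KEYS = {"id", "kind", "height", "width", "length", "lane_id", "footprint"}
_PORT_KEYS = {"id", "diameter", "lane_id", "role"}
_TOP_KEYS = {"name", "rails", "ports", "lr_footprint", "fluids"}


def device_to_dict(spec: DeviceSpec) -> dict:
    """Serialize to the μm-based JSON structure (lossless for the
    declared unit pairs: conversions are exact powers of ten)."""
    rails = []
    for r in spec.rails:
        d = {
            "id": r.id,
            "kind": r.kind.value,
            "height": m_to_um(r.height),
            "width": m_to_um(r.width),
            "length": m_to_um(r.length),
        }
        if r.lane_id is not None:
            d["lane_id"] = r.lane_id
        if r.footprint is not None:
            d["footprint"] = [[m_to_um(x), m_to_um(y)] for x, y in r.footprint]
        rails.append(d)
    ports = [
        {"id": p.id, "diameter": m_to_um(p.diameter), "lane_id": p.lane_id, "role": p.role.value}
        for p in spec.ports
    ]
    return {
        "name": spec.name,
        "rails": rails,
        "ports": ports,
        "lr_footprint": [[m_to_um(x), m_to_um(y)] for x, y in spec.lr_footprint],
    }


def _check_length(errors, ctx, key, value):
    if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
        errors.append(f"{ctx}.{key}: must be a finite number (μm), got {value!r}")
        return None
    if value <= 0:
        errors.append(f"{ctx}.{key}: must be > 0 μm, got {value}")
        return None
    return um_to_m(float(value))


def _parse_polygon(errors, ctx, value):
    if not isinstance(value, list) or any(
        not (isinstance(p, (list, tuple)) and len(p) == 2) for p in value
    ):
        errors.append(f"{ctx}: must be a list of [x, y] μm pairs")
        return ()
    return tuple((um_to_m(float(x)), um_to_m(float(y))) for x, y in value)


def device_from_dict(data: dict, source: str = "<dict>") -> DeviceSpec:
    """Parse and schema-check the μm-based JSON structure.

    All schema failures are reported together in one
    :class:`DeviceParseError`.  Physical/structural invariants beyond
    the schema are the job of
    :func:`~railpattern.geometry.validate_device`.
    """
    errors: list[str] = []
    if not isinstance(data, dict):
        raise DeviceParseError(["top level must be a JSON object"], source)
    unknown = set(data) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    name = data.get("name")
    if not isinstance(name, str) or not name:
        errors.append("name: required non-empty string")
        name = "<unnamed>"

    rails: list[RailSegment] = []
    raw_rails = data.get("rails")
    if not isinstance(raw_rails, list) or not raw_rails:
        errors.append("rails: required non-empty list")
        raw_rails = []
    for i, r in enumerate(raw_rails):
        ctx = f"rails[{i}]"
        if not isinstance(r, dict):
            errors.append(f"{ctx}: must be an object")
            continue
        unknown = set(r) - _RAIL_KEYS
        if unknown:
            errors.append(f"{ctx}: unknown keys {sorted(unknown)}")
        rid = r.get("id")
        if not isinstance(rid, str) or not rid:
            errors.append(f"{ctx}.id: required non-empty string")
            rid = f"rail{i}"
        kind_raw = r.get("kind")
        try:
            kind = RailKind(kind_raw)
        except ValueError:
            errors.append(f"{ctx}.kind: must be HIGH or LOW, got {kind_raw!r}")
            kind = RailKind.LOW
        dims = {k: _check_length(errors, ctx, k, r.get(k, -1)) for k in ("height", "width", "length")}
        lane_id = r.get("lane_id")
        if lane_id is not None and not isinstance(lane_id, str):
            errors.append(f"{ctx}.lane_id: must be a string")
            lane_id = None
        fp = None
        if "footprint" in r:
            fp = _parse_polygon(errors, f"{ctx}.footprint", r["footprint"]) or None
        if None not in dims.values():
            rails.append(
                RailSegment(
                    id=rid, kind=kind, height=dims["height"], width=dims["width"],
                    length=dims["length"], lane_id=lane_id, footprint=fp,
                )
            )

    ports: list[Port] = []
    raw_ports = data.get("ports")
    if not isinstance(raw_ports, list) or not raw_ports:
        errors.append("ports: required non-empty list")
        raw_ports = []
    for i, p in enumerate(raw_ports):
        ctx = f"ports[{i}]"
        if not isinstance(p, dict):
            errors.append(f"{ctx}: must be an object")
            continue
        unknown = set(p) - _PORT_KEYS
        if unknown:
            errors.append(f"{ctx}: unknown keys {sorted(unknown)}")
        pid = p.get("id")
        if not isinstance(pid, str) or not pid:
            errors.append(f"{ctx}.id: required non-empty string")
            pid = f"port{i}"
        diam = _check_length(errors, ctx, "diameter", p.get("diameter", -1))
        lane_id = p.get("lane_id")
        if not isinstance(lane_id, str) or not lane_id:
            errors.append(f"{ctx}.lane_id: required non-empty string")
            lane_id = "<none>"
        role_raw = p.get("role", "OPEN")
        try:
            role = PortRole(role_raw)
        except ValueError:
            errors.append(f"{ctx}.role: must be ASPIRATION or OPEN, got {role_raw!r}")
            role = PortRole.OPEN
        if diam is not None:
            ports.append(Port(id=pid, diameter=diam, lane_id=lane_id, role=role))

    lr_fp = ()
    if "lr_footprint" in data:
        lr_fp = _parse_polygon(errors, "lr_footprint", data["lr_footprint"])

    if errors:
        raise DeviceParseError(errors, source)
    return DeviceSpec(name=name, rails=tuple(rails), ports=tuple(ports), lr_footprint=lr_fp)


def load_inline_fluids(data: dict) -> dict[str, Fluid]:
    """Parse the optional inline ``fluids`` block of a device file."""
    out: dict[str, Fluid] = {}
    for name, f in (data.get("fluids") or {}).items():
        out[name] = Fluid(
            name=name,
            surface_tension=mn_per_m_to_n_per_m(float(f["surface_tension"])),
            receding_contact_angle=math.radians(float(f.get("receding_contact_angle_deg", 0.0))),
            viscosity=float(f.get("viscosity", 0.0)) * 1e-3,
        )
    return out


def load_device(path: Union[str, Path]) -> DeviceSpec:
    """Read and schema-validate a device JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise DeviceParseError([f"invalid JSON: {e}"], str(path)) from e
    return device_from_dict(data, source=str(path))


def save_device(spec: DeviceSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(device_to_dict(spec), indent=2, sort_keys=True))


def write_phase_diagram_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a phase-diagram table (columns x_um, y_um, outcome_class,
    is_boundary) to CSV.  No partial file is left behind on failure."""
    required = ["x_um", "y_um", "outcome_class", "is_boundary"]
    if table is None or len(table) == 0:
        raise ValueError("phase-diagram table is empty")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        table[required].to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if tmp.exists():  # pragma: no cover - failure path
            tmp.unlink()


def report(result, format: str = "json") -> str:
    """Render any module output as versioned JSON (sorted keys, hence
    byte-identical across identical runs) or a short plain-text block."""
    if hasattr(result, "as_dict"):
        payload = result.as_dict()
    elif isinstance(result, pd.DataFrame):
        payload = result.to_dict(orient="list")
    elif isinstance(result, dict):
        payload = result
    else:
        raise TypeError(f"cannot report object of type {type(result).__name__}")
    if format == "json":
        return json.dumps({"schema_version": 1, **payload}, indent=2, sort_keys=True)
    if format == "text":
        lines = []
        for k, v in payload.items():
            if isinstance(v, float):
                unit = " Pa" if k.endswith("_pa") else ""
                lines.append(f"{k}: {v:.4g}{unit}")
            else:
                lines.append(f"{k}: {v}")
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}")
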