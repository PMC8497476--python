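"""Closed-form critical capillary pressures and design rules.

During aspiration the liquid pressure p_l drops below the ambient p_a
and every pinned gas–liquid interface of the loaded hydrogel precursor
caves inward.  Each interface withstands a maximum (critical) pressure
difference before its contact line recedes, set by the Young–Laplace
relation evaluated at the receding contact angle:

* open port of diameter D (hemispherical cap):   Δp_O = 4γ/D
* side meniscus under a low rail of gap h:       Δp_L = 2γ·cosθ_R,c/h  (+ γ/η optional)
* lane meniscus under a high rail (gap H, width w_H):
      Δp_H = 2γ(1/w_H + 1/H)        [FACTOR2 convention, default]
      Δp_H =  γ(1/w_H + 1/H)        [SINGLE_INTERFACE convention]

Patterning succeeds when the low-rail meniscus outlasts both the open
port and the high-rail lane (Δp_L largest); the relative order of Δp_O
and Δp_H only decides whether the lane clears continuously or stepwise.
Because every pressure is linear in γ, the classification and both
design boundaries (D = 2h and H = h·w_H/(w_H − h)) are independent of
the fluid.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import BoundaryWarning, ConfigError, DomainError, NoSolutionError
from .geometry import (
    DEFAULT_OPTIONS,
    DeviceSpec,
    Fluid,
    HRConvention,
    PortRole,
    PressureModelOptions,
)

__all__ = [
    "CriticalPressureSet",
    "OutcomeClass",
    "open_port_pressure",
    "low_rail_pressure",
    "high_rail_pressure",
    "critical_pressures",
    "classify_outcome",
    "boundary_port_diameter",
    "boundary_high_rail",
    "safe_aspiration_window",
    "phase_diagram",
    "boundary_polyline",
]


@dataclass(frozen=True)
class CriticalPressureSet:
    """The three critical pressures (Pa) of one lane/device geometry."""

    dp_open: float
    dp_low: float
    dp_high: float
    convention: HRConvention
    fluid_name: str

    def as_dict(self) -> dict:
        return {
            "dp_open_pa": self.dp_open,
            "dp_low_pa": self.dp_low,
            "dp_high_pa": self.dp_high,
            "convention": self.convention.value,
            "fluid_name": self.fluid_name,
        }


class OutcomeClass(str, Enum):
    """Patterning outcome from the ordering of the three pressures.

    SUCCESS_CONTINUOUS : Δp_L > Δp_O > Δp_H — once the open port bursts
        the liquid pressure is already low enough for the lane interface
        to recede without pause.
    SUCCESS_STEPWISE   : Δp_L > Δp_H > Δp_O — the port bursts first and
        further suction then drives recession along the lane.
    FAIL_LR_BEFORE_PORT: Δp_O ≥ Δp_L — the low-rail side menisci give
        way before the open port ever bursts.
    FAIL_LR_AFTER_PORT : Δp_O < Δp_L ≤ Δp_H — the port bursts, but the
        low rail fails before the lane interface can recede.
    """

    SUCCESS_CONTINUOUS = "SUCCESS_CONTINUOUS"
    SUCCESS_STEPWISE = "SUCCESS_STEPWISE"
    FAIL_LR_BEFORE_PORT = "FAIL_LR_BEFORE_PORT"
    FAIL_LR_AFTER_PORT = "FAIL_LR_AFTER_PORT"

    @property
    def is_success(self) -> bool:
        return self in (OutcomeClass.SUCCESS_CONTINUOUS, OutcomeClass.SUCCESS_STEPWISE)


def open_port_pressure(fluid: Fluid, diameter: float) -> float:
    """Critical pressure 4γ/D of the hemispherical cap pinned at an open
    port of diameter ``diameter`` (m).  Returns Pa."""
    if not diameter > 0:
        raise DomainError(f"port diameter must be > 0, got {diameter}")
    return 4.0 * fluid.surface_tension / diameter


def _cos_theta(fluid: Fluid, options: PressureModelOptions) -> float:
    if options.cos_theta_override is not None:
        return options.cos_theta_override
    return float(np.cos(fluid.receding_contact_angle))


def low_rail_pressure(
    fluid: Fluid, low_height: float, options: PressureModelOptions = DEFAULT_OPTIONS
) -> float:
    """Critical pressure 2γ·cosθ_R,c/h of the side meniscus under a low
    rail of gap ``low_height`` (m), plus the optional in-plane curvature
    term γ/η.  Returns Pa."""
    if not low_height > 0:
        raise DomainError(f"low rail height must be > 0, got {low_height}")
    gamma = fluid.surface_tension
    p = 2.0 * gamma * _cos_theta(fluid, options) / low_height
    if options.include_eta_term:
        if options.eta is None:  # defensive; options validate on construction
            raise ConfigError("include_eta_term requires eta")
        p += gamma / options.eta
    return p


def high_rail_pressure(
    fluid: Fluid,
    high_height: float,
    high_width: float,
    options: PressureModelOptions = DEFAULT_OPTIONS,
) -> float:
    """Critical pressure of the lane meniscus under a high rail of gap
    ``high_height`` (m) and width ``high_width`` (m).  FACTOR2 returns
    2γ(1/w_H + 1/H); SINGLE_INTERFACE returns γ(1/w_H + 1/H)."""
    if not high_height > 0:
        raise DomainError(f"high rail height must be > 0, got {high_height}")
    if not high_width > 0:
        raise DomainError(f"high rail width must be > 0, got {high_width}")
    base = fluid.surface_tension * (1.0 / high_width + 1.0 / high_height)
    if options.hr_convention is HRConvention.FACTOR2:
        return 2.0 * base
    return base


GeometryTuple = tuple  # (D, h, H, w_H) in metres


def _lane_entry_port(device: DeviceSpec, lane_id: str):
    """The port through which air infiltrates a lane: its OPEN port, or
    for the aspiration lane its non-aspirating port.  With two OPEN
    ports the larger one bursts first and governs."""
    lane = device.lane(lane_id)
    asp = [p for p in lane.ports if p.role is PortRole.ASPIRATION]
    opens = [p for p in lane.ports if p.role is PortRole.OPEN]
    if asp:
        if not opens:
            raise ConfigError(
                f"lane {lane_id!r} has only the aspiration port: air cannot enter"
            )
        return max(opens, key=lambda p: p.diameter)
    if not opens:
        raise ConfigError(f"lane {lane_id!r} has no port: air cannot enter")
    return max(opens, key=lambda p: p.diameter)


def critical_pressures(
    geometry: Union[DeviceSpec, GeometryTuple],
    fluid: Fluid,
    options: PressureModelOptions = DEFAULT_OPTIONS,
    lane_id: Optional[str] = None,
) -> CriticalPressureSet:
    """Evaluate the (Δp_O, Δp_L, Δp_H) triple for one lane geometry.

    ``geometry`` is either a ``(D, h, H, w_H)`` tuple in metres or a
    :class:`DeviceSpec`, in which case the lane's air-entry (OPEN) port
    supplies D, the minimum LOW-rail gap supplies h, and the lane's HIGH
    segment supplies H and w_H.  For multi-lane devices pass ``lane_id``.
    """
    if isinstance(geometry, DeviceSpec):
        device = geometry
        if lane_id is None:
            ids = device.lane_ids
            if len(ids) != 1:
                raise ConfigError(
                    f"device {device.name!r} has {len(ids)} lanes; pass lane_id"
                )
            lane_id = ids[0]
        port = _lane_entry_port(device, lane_id)
        lane = device.lane(lane_id)
        d = port.diameter
        h = device.min_low_height
        # with several HIGH segments the hardest one governs recession
        hp = max(
            high_rail_pressure(fluid, seg.height, seg.width, options)
            for seg in lane.segments
        )
        return CriticalPressureSet(
            dp_open=open_port_pressure(fluid, d),
            dp_low=low_rail_pressure(fluid, h, options),
            dp_high=hp,
            convention=options.hr_convention,
            fluid_name=fluid.name,
        )

    d, h, hh, w = geometry
    return CriticalPressureSet(
        dp_open=open_port_pressure(fluid, d),
        dp_low=low_rail_pressure(fluid, h, options),
        dp_high=high_rail_pressure(fluid, hh, w, options),
        convention=options.hr_convention,
        fluid_name=fluid.name,
    )


def classify_outcome(pressures: CriticalPressureSet) -> OutcomeClass:
    """Classify a pressure triple into the four patterning outcomes.

    Total over all strict orderings; exact ties are measure-zero but
    still resolve deterministically (per the ≥/≤ conventions in
    :class:`OutcomeClass`) and emit a :class:`BoundaryWarning`.
    """
    dpo, dpl, dph = pressures.dp_open, pressures.dp_low, pressures.dp_high
    if dpo == dpl or dpl == dph or (dpo == dph and dph < dpl):
        _warnings.warn(
            "two critical pressures are exactly equal; geometry lies on a design boundary",
            BoundaryWarning,
            stacklevel=2,
        )
    if dpo >= dpl:
        return OutcomeClass.FAIL_LR_BEFORE_PORT
    if dpl <= dph:
        return OutcomeClass.FAIL_LR_AFTER_PORT
    if dpo >= dph:
        return OutcomeClass.SUCCESS_CONTINUOUS
    return OutcomeClass.SUCCESS_STEPWISE


def boundary_port_diameter(low_height: float) -> float:
    """Port diameter D* = 2h at which Δp_O = Δp_L: below it the low rail
    bursts before the port.  Fluid-independent (γ cancels)."""
    if not low_height > 0:
        raise DomainError(f"low rail height must be > 0, got {low_height}")
    return 2.0 * low_height


def boundary_high_rail(low_height: float, high_width: float) -> float:
    """High-rail gap H* = h·w_H/(w_H − h) at which Δp_L = Δp_H under the
    FACTOR2 convention; below it the lane interface out-pins the low
    rail and patterning fails.  For w_H = 1 mm this is the familiar
    H = h/(1 − h) with lengths in millimetres."""
    if not low_height > 0:
        raise DomainError(f"low rail height must be > 0, got {low_height}")
    if not high_width > 0:
        raise DomainError(f"high rail width must be > 0, got {high_width}")
    if low_height >= high_width:
        raise NoSolutionError(
            f"no positive boundary: low height {low_height} >= high width {high_width}"
        )
    return low_height * high_width / (high_width - low_height)


def safe_aspiration_window(pressures: CriticalPressureSet) -> Optional[tuple[float, float]]:
    """Open interval of applied suctions (Pa) predicted to clear the
    lane while the low rail stays pinned: (max(Δp_O, Δp_H), Δp_L).
    Returns None when the window is empty."""
    lo = max(pressures.dp_open, pressures.dp_high)
    hi = pressures.dp_low
    if lo >= hi:
        return None
    return (lo, hi)


# Default sweep grids (μm): spans of the experimentally probed designs.
DEFAULT_GRIDS = {
    "D_vs_h": {"h_um": (50.0, 300.0, 5.0), "D_um": (100.0, 1000.0, 10.0)},
    "H_vs_h": {"h_um": (50.0, 300.0, 5.0), "H_um": (100.0, 500.0, 5.0)},
}


def _axis_values(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    vals = start + step * np.arange(n)
    return vals[vals <= stop + 1e-9]


def boundary_polyline(axis: str, x_um: Iterable[float], fixed: dict) -> np.ndarray:
    """Closed-form boundary y*(x) in μm along the sweep axis.

    ``D_vs_h`` → D* = 2h;  ``H_vs_h`` → H* = h·w_H/(w_H − h).
    """
    x = np.asarray(list(x_um), dtype=float)
    if axis == "D_vs_h":
        return 2.0 * x
    if axis == "H_vs_h":
        w = float(fixed["w_um"])
        out = np.full_like(x, np.nan)
        ok = x < w
        out[ok] = x[ok] * w / (w - x[ok])
        return out
    raise ConfigError(f"unknown axis {axis!r}")


def phase_diagram(
    axis: str,
    grid: Optional[dict] = None,
    fixed: Optional[dict] = None,
    fluid: Optional[Fluid] = None,
    options: PressureModelOptions = DEFAULT_OPTIONS,
) -> pd.DataFrame:
    """Classify a dense (x, y) grid of geometries.

    ``axis`` is ``"D_vs_h"`` (x = h, y = D; fixed H_um, w_um) or
    ``"H_vs_h"`` (x = h, y = H; fixed D_um, w_um).  ``grid`` maps axis
    names to (start, stop, step) in μm; defaults span the experimentally
    probed designs.  The outcome is fluid-independent, so ``fluid``
    defaults to a unit-γ stand-in.  ``is_boundary`` marks, per x column,
    the grid cell nearest the closed-form boundary; the exact polyline
    is available from :func:`boundary_polyline`.

    Returns a DataFrame with columns x_um, y_um, outcome_class,
    is_boundary.
    """
    if axis not in ("D_vs_h", "H_vs_h"):
        raise ConfigError(f"unknown axis {axis!r}")
    fixed = dict(fixed or {})
    if axis == "D_vs_h":
        fixed.setdefault("H_um", 300.0)
        fixed.setdefault("w_um", 1000.0)
    else:
        fixed.setdefault("D_um", 600.0)
        fixed.setdefault("w_um", 1000.0)
    for k, v in fixed.items():
        if not v > 0:
            raise ConfigError(f"fixed dimension {k}={v} must be > 0")
    g = dict(DEFAULT_GRIDS[axis])
    if grid:
        g.update(grid)
    xs = _axis_values(*g["h_um"])
    ys = _axis_values(*g["D_um" if axis == "D_vs_h" else "H_um"])
    if xs.size == 0 or ys.size == 0:
        raise ConfigError("degenerate grid: zero points on an axis")

    if fluid is None:
        fluid = Fluid(name="unit", surface_tension=1.0)

    um = 1e-6
    rows = []
    ystar = boundary_polyline(axis, xs, fixed)
    for xi, x in enumerate(xs):
        # nearest cell to the boundary in this column (if boundary in range)
        if np.isfinite(ystar[xi]) and ys.min() <= ystar[xi] <= ys.max():
            j_boundary = int(np.argmin(np.abs(ys - ystar[xi])))
        else:
            j_boundary = -1
        for j, y in enumerate(ys):
            if axis == "D_vs_h":
                geom = (y * um, x * um, fixed["H_um"] * um, fixed["w_um"] * um)
            else:
                geom = (fixed["D_um"] * um, x * um, y * um, fixed["w_um"] * um)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", BoundaryWarning)
                oc = classify_outcome(critical_pressures(geom, fluid, options))
            rows.append((x, y, oc.value, j == j_boundary))
    return pd.DataFrame(rows, columns=["x_um", "y_um", "outcome_class", "is_boundary"])
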