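"""Quasi-static, event-ordered simulation of a single aspiration.

The liquid body under the whole rail footprint is continuous, so one
aspiration port lowers the liquid pressure everywhere at once.  As the
applied suction Δp = p_a − p_l rises monotonically from zero, each
pinned interface bursts the moment Δp crosses its critical pressure.
The model is purely quasi-static: there is no time axis, no viscosity
and no flow rate — event order is threshold order.  Air enters a lane
through its open port (threshold 4γ/D) and then recedes under the high
rail (threshold Δp_H), so a lane clears at max(Δp_O, Δp_H).  Interfaces
preferentially burst at the largest opposing port first, which is what
makes the formation order of multiple channels designable.

A lane with two equal-diameter open ports admits air from both ends
simultaneously; the two menisci meet and trap a liquid film whose
rupture needs extra pressure (a foam film carries two interfaces).  The
model treats such lanes as never clearing unless an explicit
``film_break_extra_pressure`` is supplied.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .exceptions import (
    ConfigError,
    DeviceValidationError,
    FilmTrapWarning,
    TieWarning,
)
from .geometry import (
    DEFAULT_OPTIONS,
    DeviceSpec,
    Fluid,
    PortRole,
    PressureModelOptions,
    validate_device,
)
from .pressures import (
    high_rail_pressure,
    low_rail_pressure,
    open_port_pressure,
)

__all__ = [
    "EventLocation",
    "EventType",
    "InterfaceEvent",
    "TieBreak",
    "SimulationConfig",
    "SimulationResult",
    "lane_clearing_threshold",
    "simulate_aspiration",
    "predicted_clearing_order",
]

LR_REGION_ID = "LR"


class EventLocation(str, Enum):
    OPEN_PORT = "OPEN_PORT"
    HR_LANE = "HR_LANE"
    LR_SIDE = "LR_SIDE"


class EventType(str, Enum):
    BURST = "BURST"
    RECEDE_START = "RECEDE_START"
    LANE_CLEARED = "LANE_CLEARED"
    LR_INVASION = "LR_INVASION"
    FILM_TRAP = "FILM_TRAP"


class TieBreak(str, Enum):
    """Deterministic ordering for interfaces with identical thresholds."""

    LEXICOGRAPHIC = "LEXICOGRAPHIC"


@dataclass(frozen=True)
class InterfaceEvent:
    threshold: float  # Pa of applied suction at which the event fires
    location: EventLocation
    location_id: str
    event_type: EventType
    order_index: int = -1

    def as_dict(self) -> dict:
        return {
            "threshold_pa": self.threshold,
            "location": self.location.value,
            "location_id": self.location_id,
            "event_type": self.event_type.value,
            "order_index": self.order_index,
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Maximum applied suction and model options for one aspiration.

    The suction ramp is monotone from 0 to ``applied_suction`` with no
    time axis.  ``film_break_extra_pressure`` (Pa) is the extra suction
    beyond the clearing threshold needed to rupture a trapped film;
    infinite by default since the model does not quantify it.
    """

    applied_suction: float
    options: PressureModelOptions = DEFAULT_OPTIONS
    tie_break: TieBreak = TieBreak.LEXICOGRAPHIC
    film_break_extra_pressure: float = math.inf

    def __post_init__(self) -> None:
        if not self.applied_suction > 0:
            raise ConfigError(f"applied_suction must be > 0, got {self.applied_suction}")
        if self.film_break_extra_pressure < 0:
            raise ConfigError("film_break_extra_pressure must be >= 0")


@dataclass
class SimulationResult:
    events: list[InterfaceEvent]
    cleared_lanes: set[str]
    retained_regions: set[str]
    warnings: list[str]
    success: bool

    def as_dict(self) -> dict:
        return {
            "events": [e.as_dict() for e in self.events],
            "cleared_lanes": sorted(self.cleared_lanes),
            "retained_regions": sorted(self.retained_regions),
            "warnings": list(self.warnings),
            "success": self.success,
        }


def _entry_port(device: DeviceSpec, lane_id: str):
    """Air-entry port of a lane and whether the lane film-traps.

    The aspiration lane's entry is its non-aspirating port (one hole for
    infiltration, never a film).  A non-aspiration lane with two open
    ports admits air through the larger first; equal diameters trap a
    film between the two advancing interfaces.
    """
    lane = device.lane(lane_id)
    opens = [p for p in lane.ports if p.role is PortRole.OPEN]
    has_asp = any(p.role is PortRole.ASPIRATION for p in lane.ports)
    if not opens:
        raise ConfigError(f"lane {lane_id!r} has no air-entry port")
    if has_asp:
        if len(opens) != 1:
            raise ConfigError(
                f"aspiration lane {lane_id!r} must have exactly one other port"
            )
        return opens[0], False
    entry = max(opens, key=lambda p: p.diameter)
    film = len(opens) == 2 and opens[0].diameter == opens[1].diameter
    return entry, film


def lane_clearing_threshold(
    device: DeviceSpec,
    lane_id: str,
    fluid: Fluid,
    options: PressureModelOptions = DEFAULT_OPTIONS,
) -> float:
    """Applied suction (Pa) at which a lane clears: air must first burst
    the lane's entry port (4γ/D) and then recede under the high rail
    (Δp_H), so the threshold is max of the two."""
    entry, _ = _entry_port(device, lane_id)
    lane = device.lane(lane_id)
    dpo = open_port_pressure(fluid, entry.diameter)
    dph = max(
        high_rail_pressure(fluid, seg.height, seg.width, options)
        for seg in lane.segments
    )
    return max(dpo, dph)


def simulate_aspiration(
    device: DeviceSpec, fluid: Fluid, config: SimulationConfig
) -> SimulationResult:
    """Run one quasi-static aspiration to ``config.applied_suction``.

    Events fire in ascending threshold order (ties broken
    lexicographically by location id, with a TIE warning).  A lane emits
    BURST at its entry port's 4γ/D and LANE_CLEARED at its clearing
    threshold; film-trapped lanes emit FILM_TRAP instead and stay
    uncleared unless ``film_break_extra_pressure`` is finite.  The
    low-rail region is a single interface at Δp_L computed from the
    minimum LOW gap (the most fragile side meniscus governs); crossing
    it emits LR_INVASION and fails the run.

    success = every lane cleared and no LR invasion.
    """
    violations = validate_device(device)
    if violations:
        raise DeviceValidationError(violations)

    opts = config.options
    warnings_out: list[str] = []

    dpl = low_rail_pressure(fluid, device.min_low_height, opts)

    # candidate events: (threshold, tie_key, location, id, type, lane or None)
    candidates: list[tuple[float, str, EventLocation, str, EventType, Optional[str]]] = []
    lane_threshold: dict[str, float] = {}
    trapped: set[str] = set()

    for lane_id in device.lane_ids:
        entry, film = _entry_port(device, lane_id)
        dpo = open_port_pressure(fluid, entry.diameter)
        lane = device.lane(lane_id)
        dph = max(
            high_rail_pressure(fluid, seg.height, seg.width, opts)
            for seg in lane.segments
        )
        threshold = max(dpo, dph)
        lane_threshold[lane_id] = threshold
        candidates.append(
            (dpo, entry.id, EventLocation.OPEN_PORT, entry.id, EventType.BURST, None)
        )
        if film:
            trapped.add(lane_id)
            candidates.append(
                (threshold, lane_id, EventLocation.HR_LANE, lane_id, EventType.FILM_TRAP, None)
            )
            warnings_out.append(f"FILM_TRAP:{lane_id}")
            _warnings.warn(
                f"lane {lane_id!r} has two equal open ports: liquid film trapped",
                FilmTrapWarning,
                stacklevel=2,
            )
            if math.isfinite(config.film_break_extra_pressure):
                candidates.append(
                    (
                        threshold + config.film_break_extra_pressure,
                        lane_id,
                        EventLocation.HR_LANE,
                        lane_id,
                        EventType.LANE_CLEARED,
                        lane_id,
                    )
                )
        else:
            candidates.append(
                (threshold, lane_id, EventLocation.HR_LANE, lane_id, EventType.LANE_CLEARED, lane_id)
            )
        if threshold == dpl:
            warnings_out.append(f"BOUNDARY:{lane_id}")

    candidates.append(
        (dpl, LR_REGION_ID, EventLocation.LR_SIDE, LR_REGION_ID, EventType.LR_INVASION, None)
    )

    # at equal threshold a port burst precedes the clearing it enables,
    # and the low-rail invasion is reported last
    type_rank = {
        EventType.BURST: 0,
        EventType.RECEDE_START: 1,
        EventType.LANE_CLEARED: 2,
        EventType.FILM_TRAP: 2,
        EventType.LR_INVASION: 3,
    }
    fired = [c for c in candidates if c[0] <= config.applied_suction]
    fired.sort(key=lambda c: (c[0], type_rank[c[4]], c[1]))

    # a tie means two distinct regions (two lanes, or a lane and the LR)
    # reach their threshold at the same suction; a lane's own port burst
    # coinciding with its clearing is not a tie
    region_thresholds = sorted(lane_threshold.values()) + [dpl]
    if len(set(region_thresholds)) != len(region_thresholds):
        warnings_out.append("TIE")
        _warnings.warn(
            "two regions share an identical threshold; lexicographic tie-break applied",
            TieWarning,
            stacklevel=2,
        )

    events = [
        InterfaceEvent(
            threshold=c[0],
            location=c[2],
            location_id=c[3],
            event_type=c[4],
            order_index=i,
        )
        for i, c in enumerate(fired)
    ]

    cleared = {c[5] for c in fired if c[4] is EventType.LANE_CLEARED and c[5]}
    invaded = any(c[4] is EventType.LR_INVASION for c in fired)
    if invaded:
        warnings_out.append("LR_INVASION")

    retained: set[str] = set()
    if not invaded:
        retained.add(LR_REGION_ID)
    retained |= {lid for lid in device.lane_ids if lid not in cleared}

    success = (cleared == set(device.lane_ids)) and not invaded
    return SimulationResult(
        events=events,
        cleared_lanes=cleared,
        retained_regions=retained,
        warnings=warnings_out,
        success=success,
    )


def predicted_clearing_order(
    device: DeviceSpec,
    fluid: Fluid,
    options: PressureModelOptions = DEFAULT_OPTIONS,
) -> list[str]:
    """Lane ids in ascending clearing-threshold order — with identical
    high-rail geometry this is descending opposing-port diameter, i.e.
    air advances from the largest port to the smallest.  Film-trapped
    lanes never clear and are omitted (with a warning); equal thresholds
    fall back to lexicographic order with a TIE warning."""
    thresholds: list[tuple[float, str]] = []
    for lane_id in device.lane_ids:
        _, film = _entry_port(device, lane_id)
        if film:
            _warnings.warn(
                f"lane {lane_id!r} film-traps and is omitted from the clearing order",
                FilmTrapWarning,
                stacklevel=2,
            )
            continue
        thresholds.append((lane_clearing_threshold(device, lane_id, fluid, options), lane_id))
    vals = [t for t, _ in thresholds]
    if len(set(vals)) != len(vals):
        _warnings.warn(
            "equal clearing thresholds; order falls back to lane-id lexicographic",
            TieWarning,
            stacklevel=2,
        )
    thresholds.sort(key=lambda tv: (tv[0], tv[1]))
    return [lane_id for _, lane_id in thresholds]
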