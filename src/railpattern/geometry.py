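"""Domain types and validation for rail-based open microfluidic devices.

A device is a set of *rails* — suspended hydrophilic plates under which
liquid is held by capillarity — bonded above a transparent film.  High
rails (HR) sit at a larger gap height ``H`` and carry through-hole
ports; after aspiration the gap under each HR becomes a hollow
microchannel ("lane").  Low rails (LR) sit at a smaller gap height ``h``
and pin the hydrogel precursor in place.  Only heights, widths and port
diameters enter the capillary-pressure model; planar footprints are
metadata used for rendering retained-pattern masks.

All lengths on these types are SI metres.  Config files and the
synthetic factories speak micrometres; see :mod:`railpattern.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .exceptions import ConfigError, DomainError


class RailKind(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"


class PortRole(str, Enum):
    ASPIRATION = "ASPIRATION"
    OPEN = "OPEN"


class HRConvention(str, Enum):
    """Convention for the high-rail critical pressure.

    FACTOR2 evaluates 2·γ(1/w_H + 1/H), the two-interface form that is
    consistent with the H = h·w/(w−h) design boundary and every
    observed patterning outcome.  SINGLE_INTERFACE evaluates
    γ(1/w_H + 1/H), the form that matches the worked numeric example of
    311.9 Pa.  The two printed statements are mutually inconsistent;
    both are kept and FACTOR2 is the default.
    """

    FACTOR2 = "FACTOR2"
    SINGLE_INTERFACE = "SINGLE_INTERFACE"


@dataclass(frozen=True)
class Fluid:
    """A hydrogel precursor or water, as it enters the capillary model.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"water_numeric"``.
    surface_tension:
        Gas–liquid interfacial tension γ in N/m.
    receding_contact_angle:
        Critical receding contact angle θ_R,c in radians.  On the
        plasma-treated surfaces this model targets it is close to zero,
        so the default is 0 (cos θ_R,c = 1).
    viscosity:
        Dynamic viscosity in Pa·s.  Informational only: the quasi-static
        model has no time axis, so viscosity never enters a threshold.
    """

    name: str
    surface_tension: float
    receding_contact_angle: float = 0.0
    viscosity: float = 0.0

    def __post_init__(self) -> None:
        if not self.surface_tension > 0:
            raise DomainError(f"surface_tension must be > 0, got {self.surface_tension}")
        if not (0 <= self.receding_contact_angle < math.pi / 2):
            raise DomainError(
                "receding_contact_angle must lie in [0, pi/2), got "
                f"{self.receding_contact_angle}"
            )
        if self.viscosity < 0:
            raise DomainError(f"viscosity must be >= 0, got {self.viscosity}")


@dataclass(frozen=True)
class RailSegment:
    """One rail plate.  ``height`` is the gap under the plate (h for LOW,
    H for HIGH); ``width`` is the in-plane width (w_l / w_H); ``length``
    the in-plane length l.  ``footprint`` is an optional planar polygon
    (metres) used only for mask rendering — path shape never enters the
    pressure model."""

    id: str
    kind: RailKind
    height: float
    width: float
    length: float
    lane_id: Optional[str] = None
    footprint: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.footprint is not None:
            object.__setattr__(
                self, "footprint", tuple((float(x), float(y)) for x, y in self.footprint)
            )


@dataclass(frozen=True)
class Port:
    """A through-hole in a high rail; diameter D in metres."""

    id: str
    diameter: float
    lane_id: str
    role: PortRole = PortRole.OPEN


@dataclass(frozen=True)
class PressureModelOptions:
    """Model conventions for the critical-pressure formulas.

    ``include_eta_term`` adds the in-plane curvature correction γ/η to
    the low-rail pressure, additive as printed; it is off by default
    because η scales with the rail length and h ≪ l makes 1/η
    negligible.  ``cos_theta_override`` replaces cos θ_R,c (normally 1
    for near-zero receding angles) for sensitivity studies.
    """

    hr_convention: HRConvention = HRConvention.FACTOR2
    include_eta_term: bool = False
    eta: Optional[float] = None
    cos_theta_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.include_eta_term and self.eta is None:
            raise ConfigError("include_eta_term requires eta (in-plane curvature radius)")
        if not self.include_eta_term and self.eta is not None:
            raise ConfigError("eta given but include_eta_term is False")
        if self.eta is not None and not self.eta > 0:
            raise ConfigError(f"eta must be > 0, got {self.eta}")
        if self.cos_theta_override is not None and not (
            0 <= self.cos_theta_override <= 1
        ):
            raise ConfigError(
                f"cos_theta_override must lie in [0, 1], got {self.cos_theta_override}"
            )


DEFAULT_OPTIONS = PressureModelOptions()


@dataclass(frozen=True)
class Lane:
    """View of one high-rail lane: its HIGH segments and its ports."""

    id: str
    segments: tuple[RailSegment, ...]
    ports: tuple[Port, ...]


@dataclass(frozen=True)
class DeviceSpec:
    """A full device: rails, ports, and the low-rail enclosure footprint.

    The fluid body beneath the whole footprint is treated as connected
    (the low rails stand off the floor), so a single aspiration port
    lowers the liquid pressure everywhere at once.
    """

    name: str
    rails: tuple[RailSegment, ...]
    ports: tuple[Port, ...]
    lr_footprint: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rails", tuple(self.rails))
        object.__setattr__(self, "ports", tuple(self.ports))
        object.__setattr__(
            self,
            "lr_footprint",
            tuple((float(x), float(y)) for x, y in self.lr_footprint),
        )

    @property
    def lane_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rails:
            if r.kind is RailKind.HIGH and r.lane_id and r.lane_id not in seen:
                seen.append(r.lane_id)
        return tuple(seen)

    def lane(self, lane_id: str) -> Lane:
        segs = tuple(
            r for r in self.rails if r.kind is RailKind.HIGH and r.lane_id == lane_id
        )
        if not segs:
            raise KeyError(f"no HIGH segment for lane {lane_id!r}")
        ports = tuple(p for p in self.ports if p.lane_id == lane_id)
        return Lane(lane_id, segs, ports)

    @property
    def lanes(self) -> tuple[Lane, ...]:
        return tuple(self.lane(lid) for lid in self.lane_ids)

    @property
    def low_segments(self) -> tuple[RailSegment, ...]:
        return tuple(r for r in self.rails if r.kind is RailKind.LOW)

    @property
    def min_low_height(self) -> float:
        lows = self.low_segments
        if not lows:
            raise DomainError(f"device {self.name!r} has no LOW rail segment")
        return min(r.height for r in lows)

    @property
    def aspiration_port(self) -> Port:
        asp = [p for p in self.ports if p.role is PortRole.ASPIRATION]
        if len(asp) != 1:
            raise DomainError(
                f"device {self.name!r} must have exactly one ASPIRATION port, "
                f"found {len(asp)}"
            )
        return asp[0]


@dataclass(frozen=True)
class Violation:
    """One broken validation rule, naming the offending field."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.field}] {self.rule}: {self.message}"


def _polygon_area(pts: Sequence[tuple[float, float]]) -> float:
    # shoelace; sign dropped
    n = len(pts)
    if n < 3:
        return 0.0
    s = 0.0
    for i in range(n):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def validate_device(spec: DeviceSpec) -> list[Violation]:
    """Check every structural invariant of a device spec.

    Returns an empty list iff the device is valid; otherwise one
    :class:`Violation` per broken rule.  Nothing is ever silently
    accepted — a malformed spec yields records, not exceptions.
    """
    out: list[Violation] = []

    for r in spec.rails:
        for attr in ("height", "width", "length"):
            v = getattr(r, attr)
            if not v > 0:
                out.append(
                    Violation(f"rails[{r.id}].{attr}", "positive", f"{attr} must be > 0, got {v}")
                )
    for p in spec.ports:
        if not p.diameter > 0:
            out.append(
                Violation(f"ports[{p.id}].diameter", "positive", f"diameter must be > 0, got {p.diameter}")
            )

    highs = [r for r in spec.rails if r.kind is RailKind.HIGH]
    lows = [r for r in spec.rails if r.kind is RailKind.LOW]
    if not highs:
        out.append(Violation("rails", "has_high", "device has no HIGH rail segment"))
    if not lows:
        out.append(Violation("rails", "has_low", "device has no LOW rail segment"))
    if highs and lows:
        max_low = max(r.height for r in lows)
        for r in highs:
            if not r.height > max_low:
                out.append(
                    Violation(
                        f"rails[{r.id}].height",
                        "high_above_low",
                        f"HIGH height {r.height} must strictly exceed every LOW height "
                        f"(max LOW = {max_low})",
                    )
                )

    for r in highs:
        if not r.lane_id:
            out.append(
                Violation(f"rails[{r.id}].lane_id", "lane_required", "HIGH segment must belong to a lane")
            )

    lane_ids = set(spec.lane_ids)
    n_asp = sum(1 for p in spec.ports if p.role is PortRole.ASPIRATION)
    if n_asp != 1:
        out.append(
            Violation("ports", "one_aspiration", f"exactly one ASPIRATION port required, found {n_asp}")
        )
    for p in spec.ports:
        if p.lane_id not in lane_ids:
            out.append(
                Violation(
                    f"ports[{p.id}].lane_id",
                    "lane_exists",
                    f"port references unknown lane {p.lane_id!r}",
                )
            )

    for lid in lane_ids:
        lane_ports = [p for p in spec.ports if p.lane_id == lid]
        if not 1 <= len(lane_ports) <= 2:
            out.append(
                Violation(
                    f"lanes[{lid}].ports",
                    "port_count",
                    f"lane must have 1 or 2 ports, found {len(lane_ports)}",
                )
            )
        elif len(lane_ports) == 1 and lane_ports[0].role is PortRole.ASPIRATION:
            # air cannot infiltrate a lane whose only hole is being sucked on
            out.append(
                Violation(
                    f"lanes[{lid}].ports",
                    "air_entry",
                    "a lane whose only port is the ASPIRATION port has no air-entry path",
                )
            )

    if spec.lr_footprint:
        if len(spec.lr_footprint) < 3 or _polygon_area(spec.lr_footprint) <= 0:
            out.append(
                Violation("lr_footprint", "nondegenerate", "footprint polygon has no area")
            )
        else:
            xs = [p[0] for p in spec.lr_footprint]
            ys = [p[1] for p in spec.lr_footprint]
            x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
            tol = 1e-12
            for r in highs:
                if r.footprint is None:
                    continue
                for x, y in r.footprint:
                    if not (x0 - tol <= x <= x1 + tol and y0 - tol <= y <= y1 + tol):
                        out.append(
                            Violation(
                                f"rails[{r.id}].footprint",
                                "enclosed",
                                "lane footprint extends outside the LR enclosure",
                            )
                        )
                        break

    return out
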