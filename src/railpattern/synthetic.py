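"""Synthetic devices, fluid fixtures, replicate areas, and pattern masks.

Everything the package computes can be exercised without any external
data: this module builds valid and invalid device geometries around the
design boundaries, multi-lane layouts with ordered port diameters,
seeded replicate-area samples for the uniformity statistic, and
rasterised retained-pattern masks that stand in for bottom-view dye
photographs.

Factory functions take lengths in micrometres (the unit every device
drawing prints) and return :class:`~railpattern.geometry.DeviceSpec`
objects in SI metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .exceptions import ConfigError, DomainError
from .geometry import DeviceSpec, Fluid, Port, PortRole, RailKind, RailSegment
from .simulate import LR_REGION_ID, SimulationResult
from .units import um_to_m

__all__ = [
    "FLUIDS",
    "get_fluid",
    "JitterModel",
    "make_basic_device",
    "make_multi_lane_device",
    "preset_device",
    "PRESETS",
    "sample_replicate_areas",
    "render_pattern_mask",
]

# Measured fluid properties (surface tension mN/m, viscosity mPa·s at a
# shear rate of 10/s).  `water_numeric` is the surface tension that the
# worked pressure values (1439 / 479.8 / 311.9 Pa) actually back out to;
# it differs slightly from the tabulated 72.9 mN/m for water at 25 °C,
# and both are kept.
FLUIDS: dict[str, Fluid] = {
    "water_table1": Fluid("water_table1", surface_tension=72.9e-3, viscosity=0.89e-3),
    "water_numeric": Fluid("water_numeric", surface_tension=71.97e-3, viscosity=0.89e-3),
    "fibrinogen_2p5": Fluid("fibrinogen_2p5", surface_tension=57.0e-3, viscosity=11.6e-3),
    "collagen_3": Fluid("collagen_3", surface_tension=61.7e-3, viscosity=59.1e-3),
}


def get_fluid(name: str) -> Fluid:
    try:
        return FLUIDS[name]
    except KeyError:
        raise ConfigError(
            f"unknown fluid {name!r}; available: {sorted(FLUIDS)}"
        ) from None


def _rect(x0: float, y0: float, x1: float, y1: float):
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def make_basic_device(
    d_um: float,
    h_um: float,
    hh_um: float,
    w_um: float,
    l_um: float,
    name: str = "basic",
    low_width_um: float = 1000.0,
) -> DeviceSpec:
    """Single-lane device: one high rail with two end ports (one used
    for aspiration), flanked by low rails.  Dimensions in μm: port
    diameter ``d_um``, low/high gaps ``h_um``/``hh_um``, rail width
    ``w_um``, rail length ``l_um``.

    The returned spec may be intentionally invalid (e.g. h ≥ H); run
    :func:`~railpattern.geometry.validate_device` to check.
    """
    m = um_to_m
    margin = low_width_um
    lane_fp = _rect(m(margin), m(margin), m(margin + l_um), m(margin + w_um))
    lr_fp = _rect(0.0, 0.0, m(l_um + 2 * margin), m(w_um + 2 * margin))
    rails = (
        RailSegment(
            id="HR1",
            kind=RailKind.HIGH,
            height=m(hh_um),
            width=m(w_um),
            length=m(l_um),
            lane_id="lane1",
            footprint=lane_fp,
        ),
        RailSegment(
            id="LR1",
            kind=RailKind.LOW,
            height=m(h_um),
            width=m(low_width_um),
            length=m(l_um),
        ),
        RailSegment(
            id="LR2",
            kind=RailKind.LOW,
            height=m(h_um),
            width=m(low_width_um),
            length=m(l_um),
        ),
    )
    ports = (
        Port(id="P_asp", diameter=m(d_um), lane_id="lane1", role=PortRole.ASPIRATION),
        Port(id="P_open", diameter=m(d_um), lane_id="lane1", role=PortRole.OPEN),
    )
    return DeviceSpec(name=name, rails=rails, ports=ports, lr_footprint=lr_fp)


def make_multi_lane_device(
    n_lanes: int,
    opposing_port_diameters_um: Sequence[float],
    aspiration_lane: str | int,
    h_um: float,
    hh_um: float,
    w_um: float,
    l_um: float = 5000.0,
    lane_ids: Optional[Sequence[str]] = None,
    extra_port_diameters_um: Optional[dict] = None,
    aspiration_port_diameter_um: Optional[float] = None,
    name: str = "multi_lane",
) -> DeviceSpec:
    """Parallel-lane array sharing one continuous low-rail body.

    Each lane gets one opposing (OPEN) port with the listed diameter;
    the aspiration lane additionally carries the ASPIRATION port
    (diameter defaults to 1.25× the largest opposing port, mirroring
    the layouts where the aspirating hole is the biggest).  A second
    OPEN port can be added to any non-aspiration lane via
    ``extra_port_diameters_um`` — give it the same diameter as the
    lane's first port to build a film-trapping lane.
    """
    diams = list(opposing_port_diameters_um)
    if len(diams) != n_lanes:
        raise ConfigError(
            f"need one opposing-port diameter per lane: {n_lanes} lanes, {len(diams)} diameters"
        )
    if lane_ids is None:
        pad = max(2, len(str(n_lanes)))
        lane_ids = [f"lane{str(i + 1).zfill(pad)}" for i in range(n_lanes)]
    lane_ids = list(lane_ids)
    if len(set(lane_ids)) != len(lane_ids):
        raise ConfigError("duplicate lane ids")
    if isinstance(aspiration_lane, int):
        aspiration_lane = lane_ids[aspiration_lane]
    if aspiration_lane not in lane_ids:
        raise ConfigError(f"aspiration lane {aspiration_lane!r} not among lane ids")

    m = um_to_m
    margin = 1000.0
    gap = w_um / 2.0
    rails: list[RailSegment] = []
    ports: list[Port] = []
    extra = dict(extra_port_diameters_um or {})

    for i, (lid, d) in enumerate(zip(lane_ids, diams)):
        y0 = margin + i * (w_um + gap)
        fp = _rect(m(margin), m(y0), m(margin + l_um), m(y0 + w_um))
        rails.append(
            RailSegment(
                id=f"HR_{lid}",
                kind=RailKind.HIGH,
                height=m(hh_um),
                width=m(w_um),
                length=m(l_um),
                lane_id=lid,
                footprint=fp,
            )
        )
        ports.append(Port(id=f"{lid}_in", diameter=m(d), lane_id=lid, role=PortRole.OPEN))
        if lid == aspiration_lane:
            asp_d = aspiration_port_diameter_um or 1.25 * max(diams)
            ports.append(
                Port(id=f"{lid}_asp", diameter=m(asp_d), lane_id=lid, role=PortRole.ASPIRATION)
            )
        elif lid in extra:
            ports.append(
                Port(id=f"{lid}_in2", diameter=m(extra[lid]), lane_id=lid, role=PortRole.OPEN)
            )

    height_um = 2 * margin + n_lanes * w_um + (n_lanes - 1) * gap
    width_total_um = l_um + 2 * margin
    rails.append(
        RailSegment(
            id="LR_body",
            kind=RailKind.LOW,
            height=m(h_um),
            width=m(height_um),
            length=m(width_total_um),
        )
    )
    lr_fp = _rect(0.0, 0.0, m(width_total_um), m(height_um))
    return DeviceSpec(name=name, rails=tuple(rails), ports=tuple(ports), lr_footprint=lr_fp)


def _preset_snu() -> DeviceSpec:
    # Three lanes whose opposing-port diameters strictly decrease so air
    # advances lane by lane from the largest port; aspiration on the
    # smallest-port lane.  All ports sit in the port-dominated regime
    # (4γ/D above the high-rail threshold) and below the low-rail limit.
    return make_multi_lane_device(
        3,
        [450.0, 350.0, 250.0],
        aspiration_lane="U",
        h_um=75.0,
        hh_um=300.0,
        w_um=1000.0,
        lane_ids=["S", "N", "U"],
        name="snu_replica",
    )


def _preset_array98() -> DeviceSpec:
    # 98-lane array; strictly decreasing distinct opposing diameters,
    # all > 2h (port bursts before the low rail) and all inside the
    # port-dominated regime; the aspiration lane's opposing hole is the
    # smallest, so that lane clears last.
    diams = np.linspace(460.0, 250.0, 98)
    return make_multi_lane_device(
        98,
        diams.tolist(),
        aspiration_lane=97,
        h_um=100.0,
        hh_um=300.0,
        w_um=1000.0,
        name="array98_replica",
    )


PRESETS = {
    "basic": lambda: make_basic_device(600, 100, 300, 1000, 5000, name="basic"),
    "ref-success": lambda: make_basic_device(300, 100, 300, 1000, 5000, name="ref_success"),
    "ref-fail-before-port": lambda: make_basic_device(300, 200, 300, 1000, 5000, name="ref_fail_before_port"),
    "ref-fail-after-port": lambda: make_basic_device(500, 175, 200, 1000, 5000, name="ref_fail_after_port"),
    "snu": _preset_snu,
    "array98": _preset_array98,
}


def preset_device(preset: str) -> DeviceSpec:
    """Build one of the named replica devices (see :data:`PRESETS`)."""
    try:
        factory = PRESETS[preset]
    except KeyError:
        raise ConfigError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}") from None
    return factory()


@dataclass(frozen=True)
class JitterModel:
    """Multiplicative-Gaussian model of replicate-area variation:
    area_i = mean_area × (1 + σ·z_i), z standard normal, negative draws
    rejected.  Multiplicative noise respects positivity and the
    scale-invariance of the uniformity statistic."""

    mean_area: float
    relative_sd: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if not self.mean_area > 0:
            raise DomainError(f"mean_area must be > 0, got {self.mean_area}")
        if self.relative_sd < 0:
            raise DomainError(f"relative_sd must be >= 0, got {self.relative_sd}")
        if self.n_replicates < 2:
            raise DomainError(f"need n_replicates >= 2, got {self.n_replicates}")


_MAX_REJECTION_RETRIES = 100


def sample_replicate_areas(model: JitterModel) -> list[float]:
    """Seeded, reproducible replicate areas from a :class:`JitterModel`.

    Non-positive draws are rejected and redrawn, up to 100 retries per
    replicate (beyond that the requested σ is treated as unusable)."""
    rng = np.random.default_rng(model.seed)
    out: list[float] = []
    for _ in range(model.n_replicates):
        for _try in range(_MAX_REJECTION_RETRIES):
            a = model.mean_area * (1.0 + model.relative_sd * rng.standard_normal())
            if a > 0:
                out.append(a)
                break
        else:
            raise DomainError(
                f"rejection sampling exceeded {_MAX_REJECTION_RETRIES} retries "
                f"(relative_sd={model.relative_sd} too large)"
            )
    return out


def render_pattern_mask(
    device: DeviceSpec, result: SimulationResult, pixel_size: float
) -> np.ndarray:
    """Rasterise the retained-hydrogel footprint after a simulation.

    Label 1 marks retained hydrogel (the low-rail region plus any
    uncleared lanes); 0 marks cleared lanes and background.  Top view,
    y-down, origin at the footprint bounding-box corner; ``pixel_size``
    is in metres per pixel.  After a low-rail invasion only uncleared
    lanes retain liquid, so the labelled area is strictly smaller than
    the full footprint.
    """
    if not pixel_size > 0:
        raise DomainError(f"pixel_size must be > 0, got {pixel_size}")
    fp = device.lr_footprint
    if len(fp) < 3:
        raise DomainError("device has a degenerate lr_footprint")
    xs = np.array([p[0] for p in fp])
    ys = np.array([p[1] for p in fp])
    x0, y0 = xs.min(), ys.min()
    nx = int(np.ceil((xs.max() - x0) / pixel_size))
    ny = int(np.ceil((ys.max() - y0) / pixel_size))
    if nx < 1 or ny < 1:
        raise DomainError("degenerate footprint: zero pixels at this pixel_size")
    mask = np.zeros((ny, nx), dtype=np.uint8)

    def _fill(poly, value):
        rr, cc = _sk_polygon(
            (np.array([p[1] for p in poly]) - y0) / pixel_size,
            (np.array([p[0] for p in poly]) - x0) / pixel_size,
            shape=mask.shape,
        )
        mask[rr, cc] = value

    lr_retained = LR_REGION_ID in result.retained_regions
    if lr_retained:
        _fill(fp, 1)
    for lane in device.lanes:
        cleared = lane.id in result.cleared_lanes
        for seg in lane.segments:
            if seg.footprint is None:
                raise DomainError(f"lane {lane.id!r} segment {seg.id!r} has no footprint")
            if cleared:
                _fill(seg.footprint, 0)
            elif not lr_retained:
                _fill(seg.footprint, 1)
    return mask
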