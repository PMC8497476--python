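"""Mean-deviation uniformity over replicate patterned areas.

Replicate-to-replicate consistency of the retained hydrogel footprint
is summarised by the mean-deviation uniformity

    U = [1 − (Max − Min) / (2·Avg)] × 100  (%)

over the measured areas.  U = 100% when every replicate has the same
area; it falls as the spread grows and can go negative for extreme
spreads (Max − Min > 2·Avg) — the formula is applied unclamped, with a
warning.  U is invariant to rescaling all areas by a common factor, so
it can be computed in μm² or raw pixels interchangeably.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = ["UniformityResult", "mean_deviation_uniformity", "measure_mask_area"]


@dataclass(frozen=True)
class UniformityResult:
    areas: tuple[float, ...]
    max_area: float
    min_area: float
    mean_area: float
    uniformity_pct: float
    unit: str = "um^2"

    def as_dict(self) -> dict:
        return {
            "n": len(self.areas),
            "max_area": self.max_area,
            "min_area": self.min_area,
            "mean_area": self.mean_area,
            "uniformity_pct": self.uniformity_pct,
            "unit": self.unit,
        }


def mean_deviation_uniformity(areas, unit: str = "um^2") -> UniformityResult:
    """U = [1 − (Max − Min)/(2·Avg)] × 100 over replicate areas.

    Requires at least two strictly positive areas.  Negative U (spread
    exceeding twice the mean) is returned as computed, with a warning.
    """
    arr = np.asarray(list(areas), dtype=float)
    if arr.size < 2:
        raise DomainError(f"need at least 2 replicate areas, got {arr.size}")
    if not np.all(arr > 0):
        raise DomainError("all areas must be > 0")
    mx = float(arr.max())
    mn = float(arr.min())
    avg = float(arr.mean())
    u = (1.0 - (mx - mn) / (2.0 * avg)) * 100.0
    if u < 0:
        _warnings.warn(
            f"uniformity is negative ({u:.1f}%): spread exceeds twice the mean area",
            UserWarning,
            stacklevel=2,
        )
    return UniformityResult(
        areas=tuple(arr.tolist()),
        max_area=mx,
        min_area=mn,
        mean_area=avg,
        uniformity_pct=u,
        unit=unit,
    )


def measure_mask_area(mask, label: int = 1, pixel_size: float = 1.0) -> float:
    """Area covered by ``label`` in a 2D label raster.

    ``pixel_size`` is the side length of one pixel (any length unit);
    the result is pixel count × pixel_size².  An absent label yields
    zero area with a warning rather than an error, since an empty
    footprint is a legitimate (failed-patterning) measurement.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise DomainError(f"mask must be 2D, got shape {arr.shape}")
    if not pixel_size > 0:
        raise DomainError(f"pixel_size must be > 0, got {pixel_size}")
    count = int(np.count_nonzero(arr == label))
    if count == 0:
        _warnings.warn(f"label {label} absent from mask; area is 0", UserWarning, stacklevel=2)
    return count * pixel_size**2
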