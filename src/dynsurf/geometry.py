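"""Pattern geometry and migration-distance zones.

Cells are initially confined to a microcontact-printed pattern (a circle or
a line).  Once the surrounding monolayer is switched on, cells migrate
outward; for the labeling-index analysis each nucleus is binned into a zone
by how far it travelled from the pattern *boundary*.  A point inside or on
the pattern has migration distance 0 and belongs to zone 0; outer zones are
concentric annuli (circles) or parallel bands (lines) of width
``zone_width``, with half-open ``(lo, hi]`` distance intervals so a point
exactly on a zone edge belongs to the inner zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatternSpec", "ZoneAssignment", "migration_distance", "assign_zone", "zone_band"]


@dataclass(frozen=True)
class PatternSpec:
    """Geometry of the initial cell pattern.

    Parameters
    ----------
    shape
        ``"circle"`` or ``"line"``.
    center
        Circle center, or any point on the line axis, in um.
    radius
        Circle radius in um (circles only).
    half_width
        Half of the line width in um (lines only); a 180-um-wide line
        pattern has ``half_width=90``.
    direction
        Unit vector along the line axis (lines only).
    zone_width
        Width of each migration-distance zone in um.  Defaults to the
        pattern radius (circles) or the full line width (lines), so one
        zone step equals one "pattern unit" of migration.
    """

    shape: str
    center: tuple[float, float] = (0.0, 0.0)
    radius: float | None = None
    half_width: float | None = None
    direction: tuple[float, float] = (1.0, 0.0)
    zone_width: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "line"):
            raise ValueError(f"shape must be 'circle' or 'line', got {self.shape!r}")
        if self.shape == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circle pattern requires radius > 0")
        else:
            if self.half_width is None or self.half_width <= 0:
                raise ValueError("line pattern requires half_width > 0")
            norm = math.hypot(*self.direction)
            if not math.isclose(norm, 1.0, rel_tol=1e-9):
                if norm == 0:
                    raise ValueError("line direction must be non-zero")
                object.__setattr__(
                    self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
                )
        if self.zone_width is None:
            default = self.radius if self.shape == "circle" else 2.0 * self.half_width
            object.__setattr__(self, "zone_width", default)
        if self.zone_width <= 0:
            raise ValueError("zone_width must be > 0")

    @property
    def boundary_extent(self) -> float:
        """Distance from the pattern axis/center to the boundary (um)."""
        return self.radius if self.shape == "circle" else self.half_width


@dataclass(frozen=True)
class ZoneAssignment:
    zone_index: int
    migration_distance: float

    def __post_init__(self) -> None:
        if (self.zone_index == 0) != (self.migration_distance == 0.0):
            raise ValueError("zone 0 iff migration distance 0")


def migration_distance(points, pattern: PatternSpec) -> np.ndarray:
    """Distance migrated from the pattern boundary, in um.

    Zero for points inside or on the pattern.  For circles this is
    ``max(0, |p - center| - radius)``; for lines it is the perpendicular
    offset from the axis beyond ``half_width`` (longitudinal position is
    ignored).  Accepts a single ``(x, y)`` pair or an ``(n, 2)`` array;
    always returns an array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) or an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    delta = pts - np.asarray(pattern.center, dtype=float)
    if pattern.shape == "circle":
        d = np.hypot(delta[:, 0], delta[:, 1]) - pattern.radius
    else:
        ux, uy = pattern.direction
        # perpendicular offset from the line axis
        offset = np.abs(delta[:, 0] * (-uy) + delta[:, 1] * ux)
        d = offset - pattern.half_width
    return np.maximum(d, 0.0)


def assign_zone(points, pattern: PatternSpec):
    """Map points to migration-distance zones.

    Zone 0 is the pattern interior (distance 0); zone ``k >= 1`` covers
    distances in ``((k-1)*w, k*w]`` where ``w = pattern.zone_width``.
    Returns a single :class:`ZoneAssignment` for a single point, else an
    integer array of zone indices.
    """
    single = np.asarray(points, dtype=float).ndim == 1
    d = migration_distance(points, pattern)
    # half-open (lo, hi]: an edge point belongs to the inner zone
    zones = np.where(d == 0.0, 0, np.ceil(d / pattern.zone_width).astype(int))
    zones = np.asarray(zones, dtype=int)
    if single:
        return ZoneAssignment(int(zones[0]), float(d[0]))
    return zones


def zone_band(zone_index: int, pattern: PatternSpec) -> tuple[float, float]:
    """Migration-distance interval ``(lo, hi]`` covered by a zone, in um."""
    if zone_index < 0:
        raise ValueError("zone_index must be >= 0")
    if zone_index == 0:
        return (0.0, 0.0)
    w = pattern.zone_width
    return ((zone_index - 1) * w, zone_index * w)
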