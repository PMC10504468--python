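"""Squarified treemap tiling of the structure panel.

Each displayed structure at a time point gets a rectangle whose area is
proportional to its occupancy; occupancy decreases from left to right.
Tiling is relative: tiles always fill the panel, and the displayed
fraction of the ensemble is communicated by the sum-of-occupancies
annotation rather than by empty space.  Tiles are grouped into vertical
strips advancing left to right (which preserves the occupancy ordering
of left edges); within that constraint, strip membership follows the
squarified heuristic (Bruls, Huizing & van Wijk), greedily keeping tile
aspect ratios close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .trajectory_io import TimeSlice, TrajectoryRecord


@dataclass(frozen=True)
class Rect:
    """A treemap tile in panel coordinates (origin top-left, y down)."""

    x: float
    y: float
    w: float
    h: float
    record: TrajectoryRecord | None = None

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, other: "Rect", tol: float = 1e-9) -> bool:
        return (
            other.x >= self.x - tol
            and other.y >= self.y - tol
            and other.x + other.w <= self.x + self.w + tol
            and other.y + other.h <= self.y + self.h + tol
        )


def _worst_aspect(strip: list[float], side: float) -> float:
    """Worst (max) tile aspect ratio if ``strip`` areas share one strip of length ``side``."""
    s = sum(strip)
    if s <= 0 or side <= 0:
        return float("inf")
    worst = 0.0
    for a in strip:
        ratio = max((side * side * a) / (s * s), (s * s) / (side * side * a))
        worst = max(worst, ratio)
    return worst


def layout_treemap(
    slice_: TimeSlice, panel_w: float, panel_h: float, x0: float = 0.0, y0: float = 0.0
) -> list[Rect]:
    """Tile the panel with one rectangle per displayed structure.

    The slice's records must already be sorted by descending occupancy
    (ties by ascending id, as :func:`~cofoldviz.trajectory_io.slice_at_time`
    produces them).  Tile area / panel area equals occupancy / total
    displayed occupancy, and the horizontal ordering of tile left edges
    follows descending occupancy.  Records with zero occupancy are
    skipped (a zero-area tile cannot be drawn).

    Returns an empty list for an empty slice; raises
    :class:`~cofoldviz.errors.ParameterError` for non-positive panel
    dimensions or a zero occupancy sum.
    """
    if panel_w <= 0 or panel_h <= 0:
        raise ParameterError("panel dimensions must be positive")
    records = [r for r in slice_.records if r.occupancy > 0]
    if not records:
        if slice_.records:
            raise ParameterError("cannot lay out a slice with zero total occupancy")
        return []
    total = sum(r.occupancy for r in records)
    panel_area = panel_w * panel_h
    # absolute target areas, in descending order (input is sorted)
    areas = [r.occupancy / total * panel_area for r in records]

    # Strips are vertical columns advancing left to right, so tile left
    # edges are non-decreasing in the descending-occupancy order; aspect
    # ratios are squarify-optimized within that constraint.
    rects: list[Rect] = []
    x = x0
    i = 0
    while i < len(areas):
        strip = [areas[i]]
        j = i + 1
        while j < len(areas) and _worst_aspect(
            strip + [areas[j]], panel_h
        ) <= _worst_aspect(strip, panel_h):
            strip.append(areas[j])
            j += 1
        strip_w = sum(strip) / panel_h
        cy = y0
        for k, a in enumerate(strip):
            th = a / strip_w
            rects.append(Rect(x, cy, strip_w, th, records[i + k]))
            cy += th
        x += strip_w
        i = j
    return rects
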