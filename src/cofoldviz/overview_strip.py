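"""Bottom-panel overview: dominant-structure nucleotide colors over time.

For each displayed time point the most occupied structure is selected
and its per-nucleotide colors (see :mod:`cofoldviz.coloring`) are drawn
as one column at the time point's horizontal axis position.  Columns
extend rightward to the next time point (the simulation output is a
step function between reported times), so the strip tiles the axis from
the first time point's x position to 1.  Scanning the strip makes it
easy to spot regions and times where the dominant structure changes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coloring import ColorMap, nucleotide_colors
from .errors import ParameterError
from .structure_model import parse_dotbracket
from .timescale import TimeAxis
from .trajectory_io import Trajectory

#: Color for matrix cells beyond the current transcript length.
BACKGROUND_COLOR = "#ffffff"


@dataclass(frozen=True)
class Column:
    """One time point's color column; spans the half-open x interval [x0, x1)."""

    time: float
    x0: float
    x1: float
    colors: tuple[str, ...]


@dataclass(frozen=True)
class OverviewMatrix:
    """Per (nucleotide position x time point) color grid of dominant structures.

    Every column's color vector has exactly ``max_length`` entries;
    index 0 is sequence position 1 (the 5' end).  Positions beyond the
    transcript length at that time use the background color.
    """

    max_length: int
    columns: tuple[Column, ...]
    background: str = BACKGROUND_COLOR


def dominant_record(traj: Trajectory, t: float):
    """The most occupied record at exact time point ``t``; ties -> lowest id."""
    recs = traj.records_at(t)
    if not recs:
        raise ParameterError(f"no records at time {t}")
    return min(recs, key=lambda r: (-r.occupancy, r.id))


def build_overview(
    traj: Trajectory, axis: TimeAxis, background: str = BACKGROUND_COLOR
) -> OverviewMatrix:
    """Build the overview matrix for a (filtered) trajectory on ``axis``.

    Column i spans x from x(t_i) to x(t_{i+1}); the last column extends
    to 1.0, so the column spans tile [x(t_first), 1] without gaps or
    overlaps.
    """
    times = traj.times
    max_len = traj.max_length
    xs = [axis.time_to_x(t) for t in times]
    columns = []
    for i, t in enumerate(times):
        rec = dominant_record(traj, t)
        cmap: ColorMap = nucleotide_colors(parse_dotbracket(rec.structure))
        colors = cmap.colors + (background,) * (max_len - cmap.n)
        x1 = xs[i + 1] if i + 1 < len(times) else 1.0
        columns.append(Column(time=t, x0=xs[i], x1=x1, colors=colors))
    return OverviewMatrix(max_length=max_len, columns=tuple(columns), background=background)
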