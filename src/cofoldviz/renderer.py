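"""Compose full figures and animations from a trajectory.

A frame shows, for one time point: (top) a treemap of the displayed
structure ensemble, each tile holding one secondary-structure drawing
colored by imaginary center, with tile area proportional to occupancy
and occupancy decreasing left to right; (bottom) the whole-simulation
overview strip on the composite linear/log time axis, with a black
vertical marker at 75% of the axis width (the end of transcription) and
a red cursor at the displayed time point.  The current time and the sum
of displayed occupancies (4 decimal places) are annotated between the
panels.

Animations are a series of such frames, one per displayed time point,
written as standalone SVG documents and optionally assembled into a GIF.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

from .coloring import UNPAIRED_COLOR
from .errors import ParameterError
from .overview_strip import BACKGROUND_COLOR, build_overview
from .rna_layout import layout_structure
from .scene import Scene, SCircle, SLine, SPolyline, SRect, SText
from .structure_model import parse_dotbracket
from .timescale import TimeAxis
from .trajectory_io import Trajectory, filter_by_occupancy, slice_at_time
from .treemap_layout import layout_treemap

#: SVG element ids used for the axis markers (stable, for downstream tooling).
END_MARKER_ID = "transcription-end-marker"
CURSOR_ID = "time-cursor"


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters.

    ``min_occupancy`` filters low-occupancy structures before drawing
    (default 0.01, i.e. at most 100 structures per time point when sums
    are <= 1); ``speed`` is the animation frame rate in frames/s;
    ``seed`` feeds the structure-layout relaxation.
    """

    min_occupancy: float = 0.01
    speed: float = 2.0
    width: float = 960.0
    height: float = 720.0
    margin: float = 40.0
    strip_fraction: float = 0.28  # height fraction of the overview strip panel
    unpaired_color: str = UNPAIRED_COLOR
    background: str = BACKGROUND_COLOR
    seed: int = 0
    layout_iterations: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ParameterError(
                f"min_occupancy must be in [0, 1], got {self.min_occupancy}"
            )
        if self.speed <= 0:
            raise ParameterError(f"speed must be positive, got {self.speed}")
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("frame dimensions must be positive")


def min_dwell_time(m: int) -> float:
    """Minimum dwell time, in milliseconds, before a frame is emitted.

    ``m`` is the maximal number of structures per time point of the
    file.  A scrub event selecting a time point for less than ``5 * m``
    milliseconds is skipped; ``m = 0`` yields 0 (empty time points are
    never skipped).
    """
    if m != int(m) or m < 0:
        raise ParameterError(f"structure count must be a non-negative integer, got {m}")
    return 5.0 * m


def _structure_seed(structure: str, seed: int) -> int:
    """Stable per-structure layout seed (same structure -> same drawing)."""
    return (zlib.crc32(structure.encode("ascii")) ^ (seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def _draw_structure(scene: Scene, rec, tile, cfg: RenderConfig, sequence: str | None) -> None:
    """Draw one structure inside its treemap tile, preserving aspect ratio."""
    pt = parse_dotbracket(rec.structure)
    layout = layout_structure(
        pt, seed=_structure_seed(rec.structure, cfg.seed), iterations=cfg.layout_iterations
    )
    coords = layout.scaled_to(tile.x, tile.y, tile.w, tile.h, margin=0.10)
    from .coloring import nucleotide_colors

    cmap = nucleotide_colors(pt, unpaired_color=cfg.unpaired_color)
    # nucleotide circle radius follows the drawing scale, clamped for legibility
    if pt.n > 1:
        import numpy as np

        d = np.hypot(*(coords[1:] - coords[:-1]).T)
        radius = min(max(float(np.median(d)) * 0.42, 0.8), 9.0)
    else:
        radius = min(tile.w, tile.h) * 0.1
    scene.add(
        SPolyline(
            points=tuple((float(x), float(y)) for x, y in coords),
            stroke="#c8c8c8",
            stroke_width=max(radius * 0.25, 0.4),
        )
    )
    for i, j, _k in pt.pairs():
        scene.add(
            SLine(
                float(coords[i - 1][0]), float(coords[i - 1][1]),
                float(coords[j - 1][0]), float(coords[j - 1][1]),
                stroke=cmap.color_at(i),
                stroke_width=max(radius * 0.3, 0.5),
            )
        )
    show_letters = sequence is not None and radius >= 4.0
    for pos in range(1, pt.n + 1):
        x, y = float(coords[pos - 1][0]), float(coords[pos - 1][1])
        scene.add(SCircle(x, y, radius, fill=cmap.color_at(pos)))
        if show_letters:
            scene.add(
                SText(x, y + radius * 0.4, sequence[pos - 1], size=radius * 1.1,
                      fill="#ffffff", anchor="middle")
            )
    scene.add(
        SText(tile.x + 4, tile.y + 12, f"id {rec.id}", size=10, fill="#555555")
    )


def build_frame_scene(traj: Trajectory, t: float, cfg: RenderConfig = RenderConfig()) -> Scene:
    """Build the display list for the frame at time ``t`` (nearest-previous)."""
    shown = filter_by_occupancy(traj, cfg.min_occupancy)
    axis = TimeAxis.from_trajectory(shown)
    if t < shown.times[0] or t > shown.times[-1]:
        warnings.warn(
            f"requested time {t} outside displayed range; clamping", stacklevel=2
        )
        t = min(max(t, shown.times[0]), shown.times[-1])
    sl = slice_at_time(shown, t)

    scene = Scene(width=cfg.width, height=cfg.height, background="#ffffff")
    m = cfg.margin
    strip_h = (cfg.height - 2 * m) * cfg.strip_fraction
    caption_h = 26.0
    panel_w = cfg.width - 2 * m
    panel_h = cfg.height - 2 * m - strip_h - caption_h
    panel_x, panel_y = m, m
    strip_x, strip_y = m, cfg.height - m - strip_h

    # top panel: occupancy treemap of structure drawings
    tiles = layout_treemap(sl, panel_w, panel_h, x0=panel_x, y0=panel_y)
    for tile in tiles:
        scene.add(
            SRect(tile.x, tile.y, tile.w, tile.h, fill="none", stroke="#dddddd",
                  stroke_width=0.8)
        )
        _draw_structure(scene, tile.record, tile, cfg, shown.sequence)
    scene.add(
        SRect(panel_x, panel_y, panel_w, panel_h, fill="none", stroke="#888888",
              stroke_width=1.0)
    )

    # caption between panels: current time and displayed ensemble fraction
    scene.add(
        SText(panel_x, strip_y - 8, f"t = {sl.time:.6g} s", size=13),
        SText(
            panel_x + panel_w, strip_y - 8,
            f"sum of occupancies: {sl.sum_occupancy:.4f}",
            size=13, anchor="end", elem_id="sum-occupancy",
        ),
    )

    # bottom panel: overview strip of dominant-structure colors
    overview = build_overview(shown, axis, background=cfg.background)
    cell_h = strip_h / overview.max_length
    for col in overview.columns:
        cx0 = strip_x + col.x0 * panel_w
        cw = max((col.x1 - col.x0) * panel_w, 0.0)
        if cw <= 0:
            continue
        for pos0, color in enumerate(col.colors):
            if color == overview.background:
                continue
            # 5' end (position 1) at the bottom of the strip
            cy = strip_y + strip_h - (pos0 + 1) * cell_h
            scene.add(SRect(cx0, cy, cw, cell_h, fill=color))
    scene.add(
        SRect(strip_x, strip_y, panel_w, strip_h, fill="none", stroke="#888888",
              stroke_width=1.0)
    )

    # axis decorations: end-of-transcription marker and time cursor
    x_end = strip_x + axis.time_to_x(axis.t_end) * panel_w
    scene.add(
        SLine(x_end, strip_y, x_end, strip_y + strip_h, stroke="#000000",
              stroke_width=2.0, elem_id=END_MARKER_ID)
    )
    x_cur = strip_x + axis.time_to_x(sl.time) * panel_w
    scene.add(
        SLine(x_cur, strip_y, x_cur, strip_y + strip_h, stroke="#ff0000",
              stroke_width=1.5, elem_id=CURSOR_ID)
    )
    for tick in axis.linear_ticks() + axis.log_ticks():
        tx = strip_x + axis.time_to_x(tick) * panel_w
        scene.add(
            SLine(tx, strip_y + strip_h, tx, strip_y + strip_h + 4, stroke="#000000"),
            SText(tx, strip_y + strip_h + 16, f"{tick:.3g}", size=9, anchor="middle"),
        )
    scene.add(
        SText(strip_x + panel_w / 2, strip_y + strip_h + 30, "time [s]", size=11,
              anchor="middle")
    )
    return scene


def render_frame(traj: Trajectory, t: float, cfg: RenderConfig = RenderConfig()) -> str:
    """Render the frame at time ``t`` as a standalone SVG document."""
    return build_frame_scene(traj, t, cfg).to_svg()


def render_animation(
    traj: Trajectory, cfg: RenderConfig = RenderConfig()
) -> list[tuple[float, str]]:
    """Render one SVG frame per displayed time point, in time order.

    Returns ``(time, svg)`` pairs; the frame duration when assembled is
    ``1 / cfg.speed`` seconds.  Filtering happens once up front, so time
    points whose structures all fall below ``min_occupancy`` produce no
    frame.
    """
    shown = filter_by_occupancy(traj, cfg.min_occupancy)
    return [(t, render_frame(shown, t, cfg)) for t in shown.times]


def frame_duration_ms(cfg: RenderConfig) -> float:
    """Duration of one animation frame in milliseconds (1000 / speed)."""
    return 1000.0 / cfg.speed


def write_animation(
    traj: Trajectory,
    cfg: RenderConfig = RenderConfig(),
    outdir: str | Path | None = None,
    gif_path: str | Path | None = None,
    raster_scale: float = 0.75,
) -> list[Path]:
    """Write animation frames to ``outdir`` and optionally a GIF.

    SVG is the canonical output; the GIF is a rasterized convenience
    (Pillow), with per-frame duration ``1000 / speed`` ms.  Returns the
    list of written SVG paths (empty if only a GIF was requested).
    """
    shown = filter_by_occupancy(traj, cfg.min_occupancy)
    written: list[Path] = []
    images = []
    for idx, t in enumerate(shown.times):
        scene = build_frame_scene(shown, t, cfg)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            path = outdir / f"frame_{idx:04d}.svg"
            path.write_text(scene.to_svg(), encoding="utf-8")
            written.append(path)
        if gif_path is not None:
            images.append(scene.to_image(scale=raster_scale))
    if gif_path is not None and images:
        images[0].save(
            gif_path,
            save_all=True,
            append_images=images[1:],
            duration=int(round(frame_duration_ms(cfg))),
            loop=0,
        )
    return written
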