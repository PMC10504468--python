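"""Minimal retained-mode drawing surface with SVG and raster backends.

The renderer builds a flat display list of primitives; :meth:`Scene.to_svg`
serializes it to a standalone SVG 1.1 document (stdlib ElementTree, no
external references), and :meth:`Scene.to_image` rasterizes the same list
with Pillow for GIF assembly.  Only the handful of shapes the figures
need are supported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from PIL import Image, ImageDraw

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class SRect:
    x: float
    y: float
    w: float
    h: float
    fill: str = "none"
    stroke: str = "none"
    stroke_width: float = 1.0
    elem_id: str | None = None


@dataclass(frozen=True)
class SLine:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str = "#000000"
    stroke_width: float = 1.0
    elem_id: str | None = None


@dataclass(frozen=True)
class SPolyline:
    points: tuple[tuple[float, float], ...]
    stroke: str = "#000000"
    stroke_width: float = 1.0
    elem_id: str | None = None


@dataclass(frozen=True)
class SCircle:
    cx: float
    cy: float
    r: float
    fill: str = "#000000"
    stroke: str = "none"
    stroke_width: float = 1.0
    elem_id: str | None = None


@dataclass(frozen=True)
class SText:
    x: float
    y: float
    text: str
    size: float = 12.0
    fill: str = "#000000"
    anchor: str = "start"  # start | middle | end
    elem_id: str | None = None


Primitive = SRect | SLine | SPolyline | SCircle | SText


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


@dataclass
class Scene:
    width: float
    height: float
    background: str = "#ffffff"
    items: list[Primitive] = field(default_factory=list)

    def add(self, *prims: Primitive) -> None:
        self.items.extend(prims)

    def to_svg(self) -> str:
        """Serialize to a standalone, self-contained SVG 1.1 document."""
        root = ET.Element(
            "svg",
            xmlns=SVG_NS,
            version="1.1",
            width=_fmt(self.width),
            height=_fmt(self.height),
            viewBox=f"0 0 {_fmt(self.width)} {_fmt(self.height)}",
        )
        ET.SubElement(
            root, "rect", x="0", y="0", width=_fmt(self.width), height=_fmt(self.height), fill=self.background
        )
        for p in self.items:
            self._emit(root, p)
        return ET.tostring(root, encoding="unicode", xml_declaration=True)

    @staticmethod
    def _emit(root: ET.Element, p: Primitive) -> None:
        attrs: dict[str, str] = {}
        if p.elem_id:
            attrs["id"] = p.elem_id
        if isinstance(p, SRect):
            el = ET.SubElement(
                root, "rect", x=_fmt(p.x), y=_fmt(p.y), width=_fmt(p.w), height=_fmt(p.h), fill=p.fill, **attrs
            )
            if p.stroke != "none":
                el.set("stroke", p.stroke)
                el.set("stroke-width", _fmt(p.stroke_width))
        elif isinstance(p, SLine):
            ET.SubElement(
                root,
                "line",
                x1=_fmt(p.x1), y1=_fmt(p.y1), x2=_fmt(p.x2), y2=_fmt(p.y2),
                stroke=p.stroke,
                **{"stroke-width": _fmt(p.stroke_width)},
                **attrs,
            )
        elif isinstance(p, SPolyline):
            ET.SubElement(
                root,
                "polyline",
                points=" ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in p.points),
                fill="none",
                stroke=p.stroke,
                **{"stroke-width": _fmt(p.stroke_width)},
                **attrs,
            )
        elif isinstance(p, SCircle):
            el = ET.SubElement(
                root, "circle", cx=_fmt(p.cx), cy=_fmt(p.cy), r=_fmt(p.r), fill=p.fill, **attrs
            )
            if p.stroke != "none":
                el.set("stroke", p.stroke)
                el.set("stroke-width", _fmt(p.stroke_width))
        elif isinstance(p, SText):
            el = ET.SubElement(
                root,
                "text",
                x=_fmt(p.x), y=_fmt(p.y),
                **{
                    "font-size": _fmt(p.size),
                    "font-family": "sans-serif",
                    "text-anchor": p.anchor,
                },
                fill=p.fill,
                **attrs,
            )
            el.text = p.text
        else:  # pragma: no cover
            raise TypeError(f"unknown primitive {p!r}")

    def to_image(self, scale: float = 1.0) -> Image.Image:
        """Rasterize the display list with Pillow (used for GIF frames)."""
        size = (max(1, round(self.width * scale)), max(1, round(self.height * scale)))
        img = Image.new("RGB", size, self.background)
        draw = ImageDraw.Draw(img)
        for p in self.items:
            if isinstance(p, SRect):
                xy = [p.x * scale, p.y * scale, (p.x + p.w) * scale, (p.y + p.h) * scale]
                fill = None if p.fill == "none" else p.fill
                outline = None if p.stroke == "none" else p.stroke
                draw.rectangle(xy, fill=fill, outline=outline)
            elif isinstance(p, SLine):
                draw.line(
                    [p.x1 * scale, p.y1 * scale, p.x2 * scale, p.y2 * scale],
                    fill=p.stroke,
                    width=max(1, round(p.stroke_width * scale)),
                )
            elif isinstance(p, SPolyline):
                draw.line(
                    [(x * scale, y * scale) for x, y in p.points],
                    fill=p.stroke,
                    width=max(1, round(p.stroke_width * scale)),
                )
            elif isinstance(p, SCircle):
                xy = [
                    (p.cx - p.r) * scale,
                    (p.cy - p.r) * scale,
                    (p.cx + p.r) * scale,
                    (p.cy + p.r) * scale,
                ]
                outline = None if p.stroke == "none" else p.stroke
                draw.ellipse(xy, fill=p.fill, outline=outline)
            elif isinstance(p, SText):
                draw.text((p.x * scale, p.y * scale), p.text, fill=p.fill, anchor={
                    "start": "ls", "middle": "ms", "end": "rs"
                }.get(p.anchor, "ls"))
        return img
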