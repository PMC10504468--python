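"""Hue mapping of base pairs by imaginary center.

Each base pair (i, j) is colored by its imaginary center c = (i+j)/2 on
the 360-degree hue circle:

    H(c) = (floor(c / 9) + 160 * c) mod 360

Because centers move in half-integer steps, consecutive centers are 80
degrees apart on the hue circle, cycling through nine base hues
(160 * 0.5k mod 360 takes exactly nine values); the floor(c/9) offset
slowly rotates that nine-color cycle with sequence position.  The design
goal is that small shifts of the imaginary center — e.g. the 0.5 shift
caused by a 1-nt bulge — give clearly distinguishable colors, so helices
can be recognized across structure plots and the overview strip.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass

from .structure_model import PairTable, imaginary_center

#: Neutral color for unpaired nucleotides (the scheme only defines pair hues).
UNPAIRED_COLOR = "#999999"
#: Saturation / lightness at which pair hues are realized as concrete colors.
SATURATION = 0.85
LIGHTNESS = 0.45


def hue_for_center(c: float) -> float:
    """Hue in degrees, in [0, 360), for imaginary center ``c``.

    Exact evaluation of ``(floor(c/9) + 160*c) mod 360``.  ``c`` is any
    positive half-integer; the smallest pair (1, 2) has c = 1.5.
    """
    return (math.floor(c / 9) + 160 * c) % 360


def hue_to_hex(hue: float, saturation: float = SATURATION, lightness: float = LIGHTNESS) -> str:
    """Realize a hue (degrees) as a hex RGB color at fixed saturation/lightness."""
    r, g, b = colorsys.hls_to_rgb((hue % 360) / 360.0, lightness, saturation)
    return "#{:02x}{:02x}{:02x}".format(round(r * 255), round(g * 255), round(b * 255))


@dataclass(frozen=True)
class ColorMap:
    """Per-pair hues and per-nucleotide colors of one structure.

    ``pair_hues`` maps each pair (i, j) to its hue in degrees; both
    nucleotides of a pair receive the identical concrete color in
    ``colors`` (index 0 = position 1).  Unpaired positions get the
    neutral color.
    """

    n: int
    pair_hues: dict[tuple[int, int], float]
    colors: tuple[str, ...]

    def color_at(self, position: int) -> str:
        """Color of a 1-based sequence position."""
        return self.colors[position - 1]


def nucleotide_colors(pt: PairTable, unpaired_color: str = UNPAIRED_COLOR) -> ColorMap:
    """Color every nucleotide of a structure by its pair's hue.

    Pairs with equal i+j (equal imaginary center, e.g. perfectly aligned
    helices) receive identical hues, which is what makes such helices
    visually identifiable as one unit.
    """
    colors = [unpaired_color] * pt.n
    pair_hues: dict[tuple[int, int], float] = {}
    for i, j, _layer in pt.pairs():
        hue = hue_for_center(imaginary_center(i, j))
        pair_hues[(i, j)] = hue
        hexcolor = hue_to_hex(hue)
        colors[i - 1] = hexcolor
        colors[j - 1] = hexcolor
    return ColorMap(n=pt.n, pair_hues=pair_hues, colors=tuple(colors))
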