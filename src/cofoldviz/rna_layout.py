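"""Deterministic 2D layout of RNA secondary structure graphs.

Nucleotides are nodes; backbone and base-pair edges connect them.  The
layout follows the spirit of force-directed structure drawing: a radial
nested-loop construction provides initial coordinates (loops as circles,
helices as parallel rails), followed by a fixed number of seeded
spring-relaxation iterations (backbone and pair edges as unit-length
springs, mild repulsion between non-adjacent nodes).  Pseudoknot pairs
(bracket layers >= 1) act as springs during relaxation but do not
participate in the radial nesting, so knotted pairs appear as extra
edges over an otherwise nested drawing.

The layout is a reproducibility contract: identical pair tables and
seeds yield bitwise-identical coordinates.  Visual equivalence with any
particular interactive drawing engine is not a goal; legibility and
determinism are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_model import PairTable

#: Rest length of backbone and base-pair springs (one "nucleotide unit").
REST_LENGTH = 1.0
#: Distance between consecutive pairs along a helix rail.
HELIX_RISE = 1.0
#: Default number of relaxation iterations.
ITERATIONS = 200


@dataclass(frozen=True)
class StructureLayout:
    """Per-nucleotide 2D coordinates, shape (n, 2), row i = position i+1."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("layout produced non-finite coordinates")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the drawing."""
        xmin, ymin = self.coords.min(axis=0)
        xmax, ymax = self.coords.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def scaled_to(
        self, x: float, y: float, w: float, h: float, margin: float = 0.08
    ) -> np.ndarray:
        """Coordinates fitted into a target rectangle, preserving aspect ratio.

        ``margin`` is the fraction of the rectangle left blank on each side.
        """
        xmin, ymin, xmax, ymax = self.bbox
        span_x = max(xmax - xmin, 1e-9)
        span_y = max(ymax - ymin, 1e-9)
        avail_w = w * (1 - 2 * margin)
        avail_h = h * (1 - 2 * margin)
        scale = min(avail_w / span_x, avail_h / span_y)
        cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
        out = (self.coords - (cx, cy)) * scale
        out[:, 0] += x + w / 2
        out[:, 1] += y + h / 2
        return out


def _loop_elements(pt: PairTable, a: int, b: int) -> list[tuple]:
    """Elements of the loop spanning positions a..b: ('s', p) or ('h', p, q).

    Only layer-0 pairs nest; pseudoknot positions count as singles.
    """
    elems: list[tuple] = []
    p = a
    while p <= b:
        q = pt.partner[p]
        if q > p and pt.layer[p] == 0:
            elems.append(("h", p, q))
            p = q + 1
        else:
            elems.append(("s", p))
            p += 1
    return elems


def _loop_radius(k: int) -> float:
    """Radius so adjacent slots on a k-slot loop circle sit ~REST_LENGTH apart."""
    if k < 3:
        return REST_LENGTH * 0.6
    return REST_LENGTH / (2 * math.sin(math.pi / k))


def _place_members(
    pt: PairTable,
    coords: np.ndarray,
    elems: list[tuple],
    center: np.ndarray,
    radius: float,
    angle0: float,
    dangle: float,
    slot0: int,
) -> None:
    """Place loop members on their circle slots and recurse into child helices."""
    s = slot0
    for el in elems:
        if el[0] == "s":
            theta = angle0 + dangle * s
            coords[el[1]] = center + radius * np.array([math.cos(theta), math.sin(theta)])
            s += 1
        else:
            _, p, q = el
            tp = angle0 + dangle * s
            tq = angle0 + dangle * (s + 1)
            coords[p] = center + radius * np.array([math.cos(tp), math.sin(tp)])
            coords[q] = center + radius * np.array([math.cos(tq), math.sin(tq)])
            _place_helix(pt, coords, p, q, center)
            s += 2


def _place_helix(pt: PairTable, coords: np.ndarray, p: int, q: int, parent_center: np.ndarray) -> None:
    """Stack the helix opened by pair (p, q) outward from its parent loop.

    coords[p] and coords[q] must already be set (on the parent circle).
    """
    mid0 = (coords[p] + coords[q]) / 2
    u = mid0 - parent_center
    norm = np.linalg.norm(u)
    u = u / norm if norm > 1e-12 else np.array([0.0, 1.0])
    half = (coords[q] - coords[p]) / 2
    # extend the stack: pairs (p+t, q-t) while directly stacked in layer 0
    t = 1
    while (
        p + t < q - t
        and pt.partner[p + t] == q - t
        and pt.layer[p + t] == 0
    ):
        m = mid0 + u * (HELIX_RISE * t)
        coords[p + t] = m - half
        coords[q - t] = m + half
        t += 1
    ip, iq = p + t - 1, q - t + 1  # innermost pair of this helix
    a, b = ip + 1, iq - 1
    if a > b:
        return
    elems = _loop_elements(pt, a, b)
    k = sum(2 if e[0] == "h" else 1 for e in elems) + 2  # +2: closing pair
    radius = _loop_radius(k)
    inner_mid = (coords[ip] + coords[iq]) / 2
    offset = math.sqrt(max(radius**2 - float(np.dot(half, half)), 0.01))
    center = inner_mid + u * offset
    ang_i = math.atan2(*(coords[ip] - center)[::-1])
    ang_j = math.atan2(*(coords[iq] - center)[::-1])
    diff = (ang_j - ang_i + math.pi) % (2 * math.pi) - math.pi
    sign = 1.0 if diff < 0 else -1.0  # walk the long way from ip around to iq
    dangle = sign * 2 * math.pi / k
    _place_members(pt, coords, elems, center, radius, ang_i, dangle, slot0=1)


def _radial_init(pt: PairTable) -> np.ndarray:
    """Nested-loop radial construction: loops as circles, helices as rails."""
    coords = np.zeros((pt.n + 1, 2))
    elems = _loop_elements(pt, 1, pt.n)
    k = sum(2 if e[0] == "h" else 1 for e in elems)
    if k == 1:
        return coords[1:]
    radius = _loop_radius(k)
    center = np.zeros(2)
    # exterior loop: start at 12 o'clock, walk clockwise
    _place_members(
        pt, coords, elems, center, radius, math.pi / 2, -2 * math.pi / k, slot0=0
    )
    return coords[1:]


def _edges(pt: PairTable) -> tuple[np.ndarray, np.ndarray]:
    """Spring edges as (m, 2) index array (0-based) plus rest lengths."""
    pairs = [(i - 1, i) for i in range(1, pt.n)]  # backbone
    pairs += [(i - 1, j - 1) for i, j, _k in pt.pairs()]  # base pairs, all layers
    rests = np.full(len(pairs), REST_LENGTH)
    return np.asarray(pairs, dtype=int).reshape(-1, 2), rests


def _relax(
    coords: np.ndarray,
    edges: np.ndarray,
    rests: np.ndarray,
    rng: np.random.Generator,
    iterations: int,
) -> np.ndarray:
    """Seeded spring relaxation with mild repulsion between non-adjacent nodes."""
    n = coords.shape[0]
    if n < 2:
        return coords.copy()
    pos = coords + rng.normal(scale=0.01, size=coords.shape)  # break symmetry
    adj = np.zeros((n, n), dtype=bool)
    if edges.size:
        adj[edges[:, 0], edges[:, 1]] = True
        adj[edges[:, 1], edges[:, 0]] = True
    np.fill_diagonal(adj, True)
    k_spring, k_rep = 1.0, 0.05
    for it in range(iterations):
        step = 0.25 * (1.0 - it / iterations) + 0.01
        disp = np.zeros_like(pos)
        if edges.size:
            d = pos[edges[:, 1]] - pos[edges[:, 0]]
            dist = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-9)
            f = (k_spring * (dist - rests) / dist)[:, None] * d
            np.add.at(disp, edges[:, 0], f)
            np.add.at(disp, edges[:, 1], -f)
        diff = pos[:, None, :] - pos[None, :, :]
        dist2 = np.maximum((diff**2).sum(axis=2), 1e-6)
        rep = k_rep / dist2
        rep[adj] = 0.0  # springs govern adjacent nodes
        rep[dist2 > 6.25] = 0.0  # short-range repulsion only (2.5 rest lengths)
        disp += (rep[:, :, None] * diff).sum(axis=1)
        mag = np.maximum(np.hypot(disp[:, 0], disp[:, 1]), 1e-12)
        scale = np.minimum(mag, step) / mag
        pos += disp * scale[:, None]
    return pos


def layout_structure(
    pt: PairTable, seed: int = 0, iterations: int = ITERATIONS
) -> StructureLayout:
    """Deterministic 2D coordinates for a secondary structure.

    Radial nested-loop initialization followed by ``iterations`` seeded
    relaxation steps.  Identical inputs and seed yield bitwise-identical
    coordinates.
    """
    init = _radial_init(pt)
    edges, rests = _edges(pt)
    rng = np.random.default_rng(seed)
    final = _relax(init, edges, rests, rng, iterations)
    return StructureLayout(coords=final)
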