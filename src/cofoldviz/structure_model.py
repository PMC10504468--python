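"""Dot-bracket parsing, pair tables, helices, and imaginary centers.

Secondary structures arrive as dot-bracket strings where matched brackets
denote base pairs and ``.`` denotes unpaired nucleotides.  Pseudoknots use
additional bracket alphabets; each alphabet forms an independent, properly
nested layer.  Positions are 1-based throughout, so the smallest possible
pair is (1, 2) with imaginary center 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import StructureError

#: Recognised bracket alphabets, one nesting layer per alphabet.
#: Layer 0 is the ordinary secondary structure; layers >= 1 are pseudoknots.
BRACKET_LAYERS: tuple[tuple[str, str], ...] = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))

_OPEN = {o: k for k, (o, _) in enumerate(BRACKET_LAYERS)}
_CLOSE = {c: k for k, (_, c) in enumerate(BRACKET_LAYERS)}
_UNPAIRED_CHAR = "."


@dataclass(frozen=True)
class PairTable:
    """Partner mapping for a dot-bracket string.

    Attributes
    ----------
    n:
        Structure length in nucleotides.
    partner:
        Tuple of length ``n + 1``; ``partner[i]`` is the 1-based pairing
        partner of position ``i`` or ``0`` if unpaired.  Index 0 is unused.
    layer:
        Tuple of length ``n + 1``; bracket-layer index of the pair at
        position ``i`` (0 for ``()``, 1 for ``[]``, ...) or ``-1`` if
        unpaired.
    """

    n: int
    partner: tuple[int, ...]
    layer: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.partner) != self.n + 1 or len(self.layer) != self.n + 1:
            raise ValueError("partner/layer arrays must have length n + 1")
        for i in range(1, self.n + 1):
            j = self.partner[i]
            if j:
                if j == i or self.partner[j] != i:
                    raise ValueError(f"inconsistent partner table at position {i}")

    def pairs(self) -> Iterator[tuple[int, int, int]]:
        """Yield ``(i, j, layer)`` for every pair, with ``i < j``, in 5'->3' order of i."""
        for i in range(1, self.n + 1):
            j = self.partner[i]
            if j > i:
                yield i, j, self.layer[i]

    def to_dotbracket(self) -> str:
        """Serialize back to dot-bracket, re-emitting brackets by layer."""
        chars = [_UNPAIRED_CHAR] * self.n
        for i, j, k in self.pairs():
            chars[i - 1] = BRACKET_LAYERS[k][0]
            chars[j - 1] = BRACKET_LAYERS[k][1]
        return "".join(chars)


@dataclass(frozen=True)
class Helix:
    """A maximal run of directly stacked pairs (i,j), (i+1,j-1), ... in one layer."""

    pairs: tuple[tuple[int, int], ...]
    layer: int

    @property
    def centers(self) -> tuple[float, ...]:
        """Imaginary center of each pair; identical across a perfect helix."""
        return tuple(imaginary_center(i, j) for i, j in self.pairs)

    @property
    def center(self) -> float:
        """The helix's shared imaginary center (of its outermost pair)."""
        return imaginary_center(*self.pairs[0])

    def __len__(self) -> int:
        return len(self.pairs)


def parse_dotbracket(s: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Each bracket alphabet is matched independently with its own stack, so
    pseudoknotted layers may cross each other but must individually nest.

    Raises
    ------
    StructureError
        On an empty string, an unknown character, or an unbalanced layer;
        carries the 1-based offending position where applicable.
    """
    if not s:
        raise StructureError("empty structure string")
    n = len(s)
    partner = [0] * (n + 1)
    layer = [-1] * (n + 1)
    stacks: list[list[int]] = [[] for _ in BRACKET_LAYERS]
    for pos, ch in enumerate(s, start=1):
        if ch == _UNPAIRED_CHAR:
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            k = _CLOSE[ch]
            if not stacks[k]:
                raise StructureError(f"unmatched closing bracket {ch!r}", position=pos)
            i = stacks[k].pop()
            partner[i], partner[pos] = pos, i
            layer[i] = layer[pos] = k
        else:
            raise StructureError(f"unknown character {ch!r}", position=pos)
    for k, stack in enumerate(stacks):
        if stack:
            o = BRACKET_LAYERS[k][0]
            raise StructureError(f"unmatched opening bracket {o!r}", position=stack[-1])
    return PairTable(n=n, partner=tuple(partner), layer=tuple(layer))


def imaginary_center(i: int, j: int) -> float:
    """Midpoint ``(i + j) / 2`` of a base pair in sequence coordinates.

    All pairs of a perfect helix share one imaginary center; a 1-nt bulge
    shifts the center of the adjacent helix by 0.5, the smallest possible
    shift.  Exact half-integer arithmetic, no rounding.
    """
    if i >= j:
        raise StructureError(f"base pair requires i < j, got ({i}, {j})")
    if i < 1:
        raise StructureError(f"positions are 1-based, got i={i}")
    return (i + j) / 2


def helices(pt: PairTable) -> list[Helix]:
    """Partition all pairs of ``pt`` into maximal stacked runs.

    Two pairs (i, j) and (i+1, j-1) in the same bracket layer stack; a run
    is extended greedily, so every pair belongs to exactly one helix.  A
    1-nt bulge breaks a helix (and shifts the imaginary center by 0.5).
    """
    out: list[Helix] = []
    seen: set[int] = set()
    for i, j, k in pt.pairs():
        if i in seen:
            continue
        run = [(i, j)]
        seen.add(i)
        while (
            i + 1 <= pt.n
            and pt.partner[i + 1] == j - 1
            and j - 1 > i + 1
            and pt.layer[i + 1] == k
        ):
            i, j = i + 1, j - 1
            run.append((i, j))
            seen.add(i)
        out.append(Helix(pairs=tuple(run), layer=k))
    return out
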