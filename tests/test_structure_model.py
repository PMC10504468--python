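"""Dot-bracket parsing, pair tables, helices, imaginary centers."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cofoldviz import StructureError, helices, imaginary_center, parse_dotbracket
from cofoldviz.structure_model import BRACKET_LAYERS


def pairs_of(s):
    return {(i, j) for i, j, _ in parse_dotbracket(s).pairs()}


def recursive_descent_pairs(s):
    """Independent oracle: match each bracket alphabet by recursive descent."""
    out = set()
    for k, (op, cl) in enumerate(BRACKET_LAYERS):
        sub = "".join(c if c in (op, cl) else "." for c in s)

        def match(lo, hi):
            p = lo
            while p <= hi:
                if sub[p - 1] == op:
                    depth, q = 1, p
                    while depth:
                        q += 1
                        depth += {op: 1, cl: -1}.get(sub[q - 1], 0)
                    out.add((p, q, k))
                    match(p + 1, q - 1)
                    p = q + 1
                else:
                    p += 1

        match(1, len(s))
    return out


@pytest.mark.parametrize(
    "s,expected",
    [
        ("((..))", {(1, 6), (2, 5)}),
        ("....", set()),
        ("((..[[..))..]]", {(1, 10), (2, 9), (5, 14), (6, 13)}),
        (".(.)", {(2, 4)}),
    ],
)
def test_parse_dotbracket_pairs(s, expected):
    assert pairs_of(s) == expected


def test_pseudoknot_layers_are_tracked():
    pt = parse_dotbracket("((..[[..))..]]")
    by_layer = {}
    for i, j, k in pt.pairs():
        by_layer.setdefault(k, set()).add((i, j))
    assert by_layer == {0: {(1, 10), (2, 9)}, 1: {(5, 14), (6, 13)}}


@pytest.mark.parametrize(
    "s,pos",
    [("((.)", 1), (".))", 2), ("(]", 2), ("(x)", 2)],
)
def test_parse_errors_carry_position(s, pos):
    with pytest.raises(StructureError) as exc:
        parse_dotbracket(s)
    assert exc.value.position == pos


def test_empty_structure_rejected():
    with pytest.raises(StructureError):
        parse_dotbracket("")


def test_partner_table_is_involutive():
    pt = parse_dotbracket("((.[.)).].")
    for i in range(1, pt.n + 1):
        j = pt.partner[i]
        if j:
            assert pt.partner[j] == i and j != i


@pytest.mark.parametrize(
    "i,j,c",
    [(25, 38, 31.5), (1, 2, 1.5), (2, 9, 5.5), (3, 9, 6.0)],
)
def test_imaginary_center(i, j, c):
    assert imaginary_center(i, j) == c


def test_bulge_shifts_center_by_half():
    # 1-nt bulge: adjacent helices' centers differ by the smallest shift, 0.5
    assert imaginary_center(3, 9) - imaginary_center(2, 9) == 0.5


def test_imaginary_center_requires_i_less_than_j():
    with pytest.raises(StructureError):
        imaginary_center(5, 5)
    with pytest.raises(StructureError):
        imaginary_center(7, 3)


@pytest.mark.parametrize(
    "s,n_helices,sizes",
    [
        ("((..))", 1, [2]),
        ("((.((..))))", 2, [2, 2]),
        (".", 0, []),
        ("(((....)))", 1, [3]),
        ("((..((..))..((..))..))", 3, [2, 2, 2]),
    ],
)
def test_helix_decomposition(s, n_helices, sizes):
    hs = helices(parse_dotbracket(s))
    assert len(hs) == n_helices
    assert sorted(len(h) for h in hs) == sorted(sizes)


def test_helix_pairs_share_one_center():
    for h in helices(parse_dotbracket("((((....))))..(((...)))")):
        assert len(set(h.centers)) == 1
        assert h.center == h.centers[0]


def test_helices_partition_all_pairs():
    pt = parse_dotbracket("((.((..)).))..((...))")
    total = sum(1 for _ in pt.pairs())
    assert sum(len(h) for h in helices(pt)) == total


# -- random balanced strings: stack matcher vs recursive-descent oracle -------

@st.composite
def balanced_dotbracket(draw, max_len=30):
    """Random structure <= max_len over all four bracket alphabets."""
    s = []

    def grow(budget, layer_pool):
        while budget[0] > 0:
            choice = draw(st.integers(0, 2))
            if choice == 0:
                s.append(".")
                budget[0] -= 1
            elif choice == 1 and budget[0] >= 2:
                op, cl = BRACKET_LAYERS[draw(st.sampled_from(layer_pool))]
                s.append(op)
                budget[0] -= 2
                grow(budget, layer_pool)
                s.append(cl)
            else:
                return

    grow([draw(st.integers(1, max_len))], [0, 1, 2, 3])
    return "".join(s) or "."


@given(balanced_dotbracket())
def test_stack_matcher_agrees_with_recursive_descent(s):
    got = set(parse_dotbracket(s).pairs())
    assert got == recursive_descent_pairs(s)


@given(balanced_dotbracket())
def test_serialization_round_trips(s):
    assert parse_dotbracket(s).to_dotbracket() == s
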