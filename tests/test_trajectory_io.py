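"""Trajectory file parsing, validation, filtering, and queries."""

import io
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cofoldviz import (
    ParameterError,
    Trajectory,
    TrajectoryFormatError,
    TrajectoryRecord,
    filter_by_occupancy,
    load_sequence,
    parse_trajectory,
    slice_at_time,
    summary_table,
    transcription_end_time,
    write_trajectory,
)


def test_minimal_file(minimal_text):
    traj = parse_trajectory(minimal_text)
    assert len(traj) == 1
    assert traj.max_length == 4
    rec = traj.records[0]
    assert (rec.id, rec.time, rec.occupancy, rec.structure) == (0, 0.1, 1.0, "....")


def test_header_order_is_irrelevant():
    a = "id time occupancy structure energy\n3 1.5 0.25 ((..)) -1.25\n"
    b = "time id structure occupancy energy\n1.5 3 ((..)) 0.25 -1.25\n"
    assert parse_trajectory(a) == parse_trajectory(b)


def test_extra_columns_ignored_and_comments_skipped():
    text = (
        "# a comment\n"
        "id foo time occupancy structure energy\n"
        "0 xyz 1.0 0.5 (...) -2.0\n"
        "# another comment\n"
        "1 abc 1.0 0.5 ..... -1.0\n"
    )
    traj = parse_trajectory(text)
    assert len(traj) == 2


@pytest.mark.parametrize(
    "row,fragment",
    [
        ("x 1.0 0.5 .... -1.0", "id"),
        ("0 abc 0.5 .... -1.0", "time"),
        ("0 1.0 1.5 .... -1.0", "occupancy"),
        ("0 1.0 0.5 ((.. -1.0", "bracket"),
        ("0 1.0 0.5 ....", "fields"),
    ],
)
def test_row_errors_carry_line_number(row, fragment):
    text = f"id time occupancy structure energy\n{row}\n"
    with pytest.raises(TrajectoryFormatError) as exc:
        parse_trajectory(text)
    assert exc.value.line == 2
    assert fragment in str(exc.value)


def test_missing_column_named_in_error():
    with pytest.raises(TrajectoryFormatError, match="occupancy"):
        parse_trajectory("id time structure energy\n")


def test_empty_file_rejected():
    with pytest.raises(TrajectoryFormatError):
        parse_trajectory("")
    with pytest.raises(TrajectoryFormatError):
        parse_trajectory("# only a comment\n")


def test_scientific_notation_accepted():
    traj = parse_trajectory(
        "id time occupancy structure energy\n0 1e-3 2.5e-1 .... -1.0e0\n"
    )
    assert traj.records[0].time == 1e-3
    assert traj.records[0].occupancy == 0.25


def test_occupancy_sum_above_one_warns():
    text = (
        "id time occupancy structure energy\n"
        "0 1.0 0.8 .... -1.0\n1 1.0 0.8 (..) -2.0\n"
    )
    with pytest.warns(UserWarning, match="sum"):
        parse_trajectory(text)


def test_shrinking_transcript_rejected():
    text = (
        "id time occupancy structure energy\n"
        "0 1.0 1.0 ..... -1.0\n0 2.0 1.0 .... -1.0\n"
    )
    with pytest.raises(TrajectoryFormatError, match="grow"):
        parse_trajectory(text)


def test_sequence_must_cover_longest_structure():
    with pytest.raises(TrajectoryFormatError, match="sequence"):
        parse_trajectory("id time occupancy structure energy\n0 1 1.0 .... -1\n", sequence="AC")


# -- sequence loading ---------------------------------------------------------

def test_load_sequence_fasta():
    assert load_sequence(">x\nacgu\n") == "ACGU"


def test_load_sequence_raw_passthrough():
    assert load_sequence("ACGUACGU") == "ACGUACGU"


def test_load_sequence_special_characters_allowed():
    assert load_sequence("NNNAA&GG") == "NNNAA&GG"


def test_load_sequence_multirecord_fasta_warns_uses_first():
    with pytest.warns(UserWarning, match="first"):
        seq = load_sequence(">a\nACGU\n>b\nGGGG\n")
    assert seq == "ACGU"


def test_load_sequence_empty_rejected():
    with pytest.raises(TrajectoryFormatError):
        load_sequence("   \n")


# -- filtering ----------------------------------------------------------------

def _traj(rows):
    recs = [TrajectoryRecord(*r) for r in rows]
    return Trajectory(recs)


def test_filter_keeps_above_threshold():
    traj = _traj(
        [(0, 1.0, 0.5, "....", -1.0), (1, 1.0, 0.3, "(..)", -1.0), (2, 1.0, 0.005, "....", 0.0)]
    )
    out = filter_by_occupancy(traj, 0.01)
    assert len(out) == 2
    assert math.isclose(slice_at_time(out, 1.0).sum_occupancy, 0.8)


def test_filter_removes_whole_time_points():
    traj = _traj(
        [(0, 1.0, 0.9, "....", -1.0), (0, 2.0, 0.005, "....", -1.0), (0, 3.0, 0.9, "....", -1.0)]
    )
    out = filter_by_occupancy(traj, 0.01)
    assert out.times == (1.0, 3.0)


def test_filter_zero_threshold_is_identity(competition_traj):
    assert filter_by_occupancy(competition_traj, 0.0) == competition_traj


def test_filter_threshold_out_of_range(competition_traj):
    with pytest.raises(ParameterError):
        filter_by_occupancy(competition_traj, 1.5)


def test_filter_is_idempotent_and_monotone(competition_traj):
    once = filter_by_occupancy(competition_traj, 0.1)
    assert filter_by_occupancy(once, 0.1) == once
    higher = filter_by_occupancy(competition_traj, 0.3)
    assert set(higher.records) <= set(once.records)


@given(st.floats(0.0, 0.5))
def test_filtered_time_points_meet_threshold(thr):
    traj = _traj(
        [(0, 1.0, 0.6, "....", -1.0), (1, 1.0, 0.4, "(..)", -1.0), (0, 2.0, 0.55, "....", -1.0)]
    )
    out = filter_by_occupancy(traj, thr)
    for t in out.times:
        assert slice_at_time(out, t).sum_occupancy >= thr


# -- slicing and queries ------------------------------------------------------

def test_slice_nearest_previous(competition_traj):
    assert slice_at_time(competition_traj, 1.5).time == 1.0
    assert slice_at_time(competition_traj, 2.0).time == 2.0
    assert slice_at_time(competition_traj, 0.01).time == 0.5


def test_slice_tie_break_by_ascending_id():
    traj = _traj([(7, 1.0, 0.4, "....", -1.0), (3, 1.0, 0.4, "(..)", -1.0)])
    sl = slice_at_time(traj, 1.0)
    # oracle: stable sort on (-occupancy, id)
    expected = sorted(traj.records, key=lambda r: (-r.occupancy, r.id))
    assert [r.id for r in sl.records] == [r.id for r in expected] == [3, 7]


def test_slice_sorted_descending_occupancy(competition_traj):
    sl = slice_at_time(competition_traj, 2.0)
    occs = [r.occupancy for r in sl.records]
    assert occs == sorted(occs, reverse=True)


def test_transcription_end_first_attainment_of_max():
    rows = []
    for t, n in zip([1.0, 2.0, 3.0, 4.0, 5.0], [10, 20, 30, 30, 30]):
        rows.append((0, t, 1.0, "." * n, -1.0))
    traj = _traj(rows)
    # oracle: linear scan for the first time the transcript is full length
    first = min(t for t, n in zip([1, 2, 3, 4, 5], [10, 20, 30, 30, 30]) if n == 30)
    assert transcription_end_time(traj) == first == 3.0


def test_transcription_end_degenerate_cases():
    assert transcription_end_time(_traj([(0, 2.0, 1.0, "....", -1.0)])) == 2.0
    traj = _traj([(0, 1.0, 1.0, "....", -1.0), (0, 5.0, 1.0, "....", -1.0)])
    assert transcription_end_time(traj) == 1.0


# -- summary table ------------------------------------------------------------

def test_summary_table_rows_and_sum(competition_traj):
    sl = slice_at_time(competition_traj, 2.0)
    table = summary_table(sl)
    assert len(table.rows) == 3
    assert [row.id for row in table.rows] == [1, 0, 2]
    # sum recomputed independently from the rows
    assert math.isclose(table.sum_occupancy, sum(r.occupancy for r in table.rows))


# -- round trip ---------------------------------------------------------------

def test_write_parse_round_trip(competition_traj, helix_competition):
    for traj in (competition_traj, helix_competition):
        out = io.StringIO()
        write_trajectory(traj, out)
        again = parse_trajectory(out.getvalue())
        assert again == traj
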