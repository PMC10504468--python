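"""Trajectory file I/O: read, validate, filter, query, and write.

A trajectory file is a plain-text, whitespace-separated table describing
the structural ensemble of a cotranscriptional folding simulation over
time.  The header line must contain (at least) the five column names

    id time occupancy structure energy

in any order; extra columns are ignored and columns are matched by name.
``id`` groups one structure lineage across transcript lengths, ``time``
is in seconds, ``occupancy`` is the ensemble fraction of the structure at
that time point, ``structure`` is a dot-bracket string (pseudoknot
bracket layers allowed), and ``energy`` is a free energy in kcal/mol.
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import io
import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, TextIO

from .errors import ParameterError, StructureError, TrajectoryFormatError
from .structure_model import parse_dotbracket

REQUIRED_COLUMNS = ("id", "time", "occupancy", "structure", "energy")

#: Per-time-point occupancy sums above 1 by more than this warn (not error):
#: aggregated stochastic trajectories can carry rounding artifacts.
OCCUPANCY_SUM_TOLERANCE = 1e-6


@dataclass(frozen=True)
class TrajectoryRecord:
    """One row of a trajectory file.

    ``id`` is an integer lineage label grouping structures across
    transcript lengths; ``time`` (s), ``occupancy`` (fraction of the
    ensemble), ``structure`` (dot-bracket), ``energy`` (kcal/mol).
    """

    id: int
    time: float
    occupancy: float
    structure: str
    energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if not math.isfinite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")
        parse_dotbracket(self.structure)  # raises StructureError if invalid

    @property
    def length(self) -> int:
        """Transcript length of this record's structure, in nucleotides."""
        return len(self.structure)


class Trajectory:
    """A validated, ordered collection of trajectory records.

    Records keep file order within a time point; ``times`` is the strictly
    increasing sorted set of record times.  Construction checks the
    physical invariants of a growing transcript: the per-time-point
    maximum structure length must be non-decreasing, and an optional
    sequence must cover the longest structure.  Per-time-point occupancy
    sums above 1 and duplicate ids within a time point produce warnings,
    not errors.
    """

    def __init__(self, records: Iterable[TrajectoryRecord], sequence: str | None = None):
        self._records: tuple[TrajectoryRecord, ...] = tuple(records)
        if not self._records:
            raise TrajectoryFormatError("trajectory contains no records")
        self._by_time: dict[float, list[TrajectoryRecord]] = {}
        for rec in self._records:
            self._by_time.setdefault(rec.time, []).append(rec)
        self._times: tuple[float, ...] = tuple(sorted(self._by_time))
        self._max_length = max(rec.length for rec in self._records)
        self.sequence = sequence
        self._validate()

    def _validate(self) -> None:
        prev_max = 0
        for t in self._times:
            recs = self._by_time[t]
            cur_max = max(r.length for r in recs)
            if cur_max < prev_max:
                raise TrajectoryFormatError(
                    f"maximum structure length decreases at time {t} "
                    f"({cur_max} < {prev_max}); the transcript can only grow"
                )
            prev_max = cur_max
            total = sum(r.occupancy for r in recs)
            if total > 1.0 + OCCUPANCY_SUM_TOLERANCE:
                warnings.warn(
                    f"occupancies at time {t} sum to {total:.6g} > 1", stacklevel=3
                )
            ids = [r.id for r in recs]
            if len(ids) != len(set(ids)):
                warnings.warn(f"duplicate structure ids at time {t}", stacklevel=3)
        if self.sequence is not None and len(self.sequence) < self._max_length:
            raise TrajectoryFormatError(
                f"sequence length {len(self.sequence)} is shorter than the "
                f"longest structure ({self._max_length} nt)"
            )

    @property
    def records(self) -> tuple[TrajectoryRecord, ...]:
        return self._records

    @property
    def times(self) -> tuple[float, ...]:
        """Strictly increasing unique time points."""
        return self._times

    @property
    def max_length(self) -> int:
        """Maximum structure length over all records (final transcript length)."""
        return self._max_length

    def records_at(self, t: float) -> tuple[TrajectoryRecord, ...]:
        """Records at the exact time point ``t``, in file order."""
        return tuple(self._by_time.get(t, ()))

    def max_length_at(self, t: float) -> int:
        """Maximum structure length among records at exact time point ``t``."""
        return max(r.length for r in self._by_time[t])

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return self._records == other._records and self.sequence == other.sequence


@dataclass(frozen=True)
class TimeSlice:
    """The displayed ensemble at one time point.

    Records are sorted by descending occupancy, ties broken by ascending
    id; ``sum_occupancy`` is the displayed fraction of the ensemble.
    """

    time: float
    records: tuple[TrajectoryRecord, ...]
    sum_occupancy: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sum_occupancy is None:
            object.__setattr__(
                self, "sum_occupancy", sum(r.occupancy for r in self.records)
            )


def _coerce_stream(text: str | TextIO) -> TextIO:
    return io.StringIO(text) if isinstance(text, str) else text


def _parse_float(token: str, column: str, line_no: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise TrajectoryFormatError(
            f"non-numeric {column} value {token!r}", line=line_no
        ) from None
    if math.isnan(value):
        raise TrajectoryFormatError(f"{column} is NaN", line=line_no)
    return value


def parse_trajectory(text: str | TextIO, sequence: str | None = None) -> Trajectory:
    """Parse a trajectory file from a string or text stream.

    The first non-empty, non-comment line is the header.  Columns are
    matched by header name, not position; unknown extra columns are
    ignored.  Numeric fields accept scientific notation; times need not
    be equally spaced.

    Raises
    ------
    TrajectoryFormatError
        Naming the missing column for a bad header, or carrying the file
        line number for a bad row (non-integer id, non-numeric fields,
        occupancy outside [0, 1], unbalanced structure).
    """
    stream = _coerce_stream(text)
    header: dict[str, int] | None = None
    records: list[TrajectoryRecord] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if header is None:
            header = {name: idx for idx, name in enumerate(tokens)}
            for col in REQUIRED_COLUMNS:
                if col not in header:
                    raise TrajectoryFormatError(f"missing required column {col!r}")
            continue
        if len(tokens) < len(header):
            raise TrajectoryFormatError(
                f"expected {len(header)} fields, got {len(tokens)}", line=line_no
            )
        id_token = tokens[header["id"]]
        try:
            rec_id = int(id_token)
        except ValueError:
            raise TrajectoryFormatError(
                f"non-integer id value {id_token!r}", line=line_no
            ) from None
        time = _parse_float(tokens[header["time"]], "time", line_no)
        occupancy = _parse_float(tokens[header["occupancy"]], "occupancy", line_no)
        energy = _parse_float(tokens[header["energy"]], "energy", line_no)
        structure = tokens[header["structure"]]
        try:
            records.append(
                TrajectoryRecord(
                    id=rec_id,
                    time=time,
                    occupancy=occupancy,
                    structure=structure,
                    energy=energy,
                )
            )
        except (ValueError, StructureError) as exc:
            raise TrajectoryFormatError(str(exc), line=line_no) from None
    if header is None:
        raise TrajectoryFormatError("empty file: no header line found")
    if not records:
        raise TrajectoryFormatError("no data rows after the header")
    return Trajectory(records, sequence=sequence)


def read_trajectory(path: str | Path, sequence: str | None = None) -> Trajectory:
    """Read a trajectory file from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_trajectory(fh, sequence=sequence)


def write_trajectory(traj: Trajectory, stream: TextIO | None = None) -> str:
    """Serialize a trajectory back to its file format.

    Floats use Python's shortest round-tripping representation, so
    parsing the output reproduces id/time/occupancy/structure exactly and
    energy to printed precision.  Returns the written text.
    """
    buf = io.StringIO()
    buf.write("id time occupancy structure energy\n")
    for rec in traj.records:
        buf.write(f"{rec.id} {rec.time!r} {rec.occupancy!r} {rec.structure} {rec.energy!r}\n")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def load_sequence(text: str | TextIO) -> str:
    """Load the nucleotide sequence accompanying a simulation.

    Accepts either a raw single-line string or FASTA (the first record is
    used; extra records produce a warning).  The sequence is uppercased
    and stripped of surrounding whitespace; arbitrary characters are
    permitted so specific positions can be annotated with special
    characters.
    """
    stream = _coerce_stream(text)
    content = stream.read()
    if not content.strip():
        raise TrajectoryFormatError("empty sequence input")
    if content.lstrip().startswith(">"):
        from Bio import SeqIO

        fasta_records = list(SeqIO.parse(io.StringIO(content), "fasta"))
        if not fasta_records:
            raise TrajectoryFormatError("no FASTA records found")
        if len(fasta_records) > 1:
            warnings.warn(
                f"{len(fasta_records)} FASTA records found; using the first",
                stacklevel=2,
            )
        return str(fasta_records[0].seq).strip().upper()
    return content.strip().upper()


def read_sequence(path: str | Path) -> str:
    """Read a sequence file (FASTA or raw) from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return load_sequence(fh)


def filter_by_occupancy(traj: Trajectory, min_occupancy: float) -> Trajectory:
    """Drop records with occupancy below ``min_occupancy``.

    Time points left with no records disappear from the result entirely,
    so filtering may remove whole time points from a visualization.  A
    threshold of 0 returns an equal trajectory.
    """
    if not 0.0 <= min_occupancy <= 1.0:
        raise ParameterError(f"min_occupancy must be in [0, 1], got {min_occupancy}")
    kept = [r for r in traj.records if r.occupancy >= min_occupancy]
    if not kept:
        raise TrajectoryFormatError(
            f"no records remain at min_occupancy={min_occupancy}"
        )
    return Trajectory(kept, sequence=traj.sequence)


def slice_at_time(traj: Trajectory, t: float) -> TimeSlice:
    """The time slice at the largest time point <= ``t``.

    Nearest-previous convention, matching a scrubbing cursor over
    discrete simulation outputs; a ``t`` before the first time point
    selects the first.  Records come sorted by descending occupancy,
    ties by ascending id.
    """
    times = traj.times
    idx = max(bisect_right(times, t) - 1, 0)
    t_sel = times[idx]
    recs = sorted(traj.records_at(t_sel), key=lambda r: (-r.occupancy, r.id))
    return TimeSlice(time=t_sel, records=tuple(recs))


def transcription_end_time(traj: Trajectory) -> float:
    """Earliest time point at which the transcript reaches its final length.

    The file format carries no explicit transcript-length column, so the
    end of transcription is detected as the first attainment of the
    maximum structure length.  If all records share one length, this is
    the first time point.
    """
    target = traj.max_length
    for t in traj.times:
        if traj.max_length_at(t) == target:
            return t
    raise AssertionError("unreachable: max_length is attained at some time point")


class SummaryRow(NamedTuple):
    id: int
    time: float
    occupancy: float
    structure: str
    energy: float


@dataclass(frozen=True)
class SummaryTable:
    """The currently displayed rows of the input file, plus their occupancy sum."""

    rows: tuple[SummaryRow, ...]
    sum_occupancy: float


def summary_table(slice_: TimeSlice) -> SummaryTable:
    """Tabulate the displayed records of a time slice, in slice order."""
    rows = tuple(
        SummaryRow(r.id, r.time, r.occupancy, r.structure, r.energy)
        for r in slice_.records
    )
    return SummaryTable(rows=rows, sum_occupancy=slice_.sum_occupancy)
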