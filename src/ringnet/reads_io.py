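"""Per-read mutation records and auxiliary inputs.

The unit of single-molecule analysis is the :class:`ReadRecord`: one sequenced
molecule's covered reference intervals, the positions where the reverse
transcriptase recorded a chemical adduct as a mutation, and the positions whose
base quality fell below the phred cutoff.  Records travel in MRF (mutation read
format), a tab-separated text dialect documented in :func:`parse_reads`.

All coordinates are 1-based; intervals are closed, matching rRNA residue
numbering conventions (e.g. C1192).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "ReferenceSequence",
    "PositionMask",
    "MRFFormatError",
    "parse_reads",
    "write_reads",
    "apply_quality_rule",
    "load_mask",
    "write_mask",
    "load_reference",
]


class MRFFormatError(ValueError):
    """Raised when an MRF file (or mask file) violates its grammar."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort intervals and merge overlapping or touching ones.

    Overlapping paired-end mates are represented as merged, non-overlapping
    intervals, so a base sequenced by both mates is counted once.
    """
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced molecule.

    Parameters
    ----------
    read_id : str
        Identifier carried through from the aligner.
    covered : tuple of (start, end)
        Closed 1-based intervals covered by the read (or read pair); sorted,
        non-overlapping.  Paired-end mates separated by a gap produce two
        intervals.
    mutations : frozenset of int
        1-based positions where a mutation (adduct readout) was recorded.
        Multi-nucleotide events are represented by their leftmost position.
    lowq : frozenset of int
        Covered positions whose base quality fell below the phred cutoff.
    """

    read_id: str
    covered: tuple[tuple[int, int], ...]
    mutations: frozenset[int]
    lowq: frozenset[int]

    def covers(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.covered)

    @property
    def covered_length(self) -> int:
        return sum(b - a + 1 for a, b in self.covered)

    def covered_positions(self) -> Iterator[int]:
        for a, b in self.covered:
            yield from range(a, b + 1)

    def validate(self, reference_length: int | None = None) -> None:
        """Check the record invariants; raise :class:`MRFFormatError` if violated."""
        prev_end = 0
        for a, b in self.covered:
            if a < 1 or b < a:
                raise MRFFormatError(f"bad interval {a}-{b} in read {self.read_id!r}")
            if a <= prev_end:
                raise MRFFormatError(
                    f"intervals overlap or are unsorted in read {self.read_id!r}"
                )
            prev_end = b
        if reference_length is not None and prev_end > reference_length:
            raise MRFFormatError(
                f"read {self.read_id!r} extends to {prev_end}, beyond reference "
                f"length {reference_length}"
            )
        for p in self.mutations:
            if not self.covers(p):
                raise MRFFormatError(
                    f"mutation at {p} outside covered intervals in read {self.read_id!r}"
                )
        for p in self.lowq:
            if not self.covers(p):
                raise MRFFormatError(
                    f"low-quality position {p} outside covered intervals in read "
                    f"{self.read_id!r}"
                )


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference sequence with 1-based indexing (``base(1)`` is the first)."""

    name: str
    bases: str

    def __post_init__(self):
        if len(self.bases) == 0:
            raise ValueError("reference sequence is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} outside 1..{len(self.bases)}")
        return self.bases[pos - 1]


@dataclass(frozen=True)
class PositionMask:
    """Set of 1-based positions excluded from all counting.

    Typically positions with a high background mutation rate in an untreated
    control (e.g. single-nucleotide polymorphisms relative to the reference).
    """

    excluded: frozenset[int]

    @classmethod
    def empty(cls) -> "PositionMask":
        return cls(frozenset())

    def __contains__(self, pos: int) -> bool:
        return pos in self.excluded

    def __len__(self) -> int:
        return len(self.excluded)

    def validate(self, reference_length: int) -> None:
        bad = [p for p in self.excluded if not 1 <= p <= reference_length]
        if bad:
            raise ValueError(f"masked positions outside 1..{reference_length}: {sorted(bad)}")


# ---------------------------------------------------------------------------
# MRF parsing / writing
# ---------------------------------------------------------------------------

def _parse_poslist(token: str, field: str, line_number: int) -> frozenset[int]:
    body = token.removeprefix(field + "=")
    if body == token:
        raise MRFFormatError(f"expected '{field}=' field, got {token!r}", line_number)
    if body == "-":
        return frozenset()
    try:
        return frozenset(int(x) for x in body.split(","))
    except ValueError:
        raise MRFFormatError(f"non-integer position in '{field}=' field: {body!r}", line_number)


def _parse_intervals(token: str, line_number: int) -> tuple[tuple[int, int], ...]:
    body = token.removeprefix("cov=")
    if body == token or body in ("", "-"):
        raise MRFFormatError(f"expected 'cov=' field with intervals, got {token!r}", line_number)
    out = []
    for part in body.split(","):
        try:
            a_s, b_s = part.split("-")
            out.append((int(a_s), int(b_s)))
        except ValueError:
            raise MRFFormatError(f"bad interval {part!r} in 'cov=' field", line_number)
    return _merge_intervals(out)


def parse_reads(path: str | Path | TextIO, reference_length: int | None = None) -> Iterator[ReadRecord]:
    """Parse an MRF file, yielding validated :class:`ReadRecord` objects in file order.

    MRF grammar (tab-separated, UTF-8)::

        #MRF<TAB>v1
        #length<TAB><L>
        <read_id><TAB>cov=<start>-<end>[,<start>-<end>...]<TAB>mut=<pos>[,...]|-<TAB>lowq=<pos>[,...]|-

    Intervals are 1-based and inclusive.  ``-`` denotes an empty position list.
    Overlapping intervals (overlapping mates) are merged on input.

    Parameters
    ----------
    path : path or open text handle
    reference_length : int, optional
        If given, overrides/validates the ``#length`` header; every record is
        checked against it.

    Raises
    ------
    MRFFormatError
        On any malformed line, with its line number.
    """
    if isinstance(path, (str, Path)):
        handle: TextIO = open(path, "rt", encoding="utf-8")
        own = True
    else:
        handle, own = path, False
    try:
        length = reference_length
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                if fields[0] == "#length":
                    try:
                        file_length = int(fields[1])
                    except (IndexError, ValueError):
                        raise MRFFormatError("bad '#length' header", lineno)
                    if length is None:
                        length = file_length
                    elif length != file_length:
                        raise MRFFormatError(
                            f"file declares length {file_length}, expected {length}", lineno
                        )
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise MRFFormatError(
                    f"expected 4 tab-separated fields, got {len(fields)}: {line!r}", lineno
                )
            read_id = fields[0]
            covered = _parse_intervals(fields[1], lineno)
            mutations = _parse_poslist(fields[2], "mut", lineno)
            lowq = _parse_poslist(fields[3], "lowq", lineno)
            record = ReadRecord(read_id, covered, mutations, lowq)
            try:
                record.validate(length)
            except MRFFormatError as exc:
                raise MRFFormatError(str(exc), lineno) from None
            yield record
    finally:
        if own:
            handle.close()


def _poslist_str(positions: frozenset[int]) -> str:
    return ",".join(str(p) for p in sorted(positions)) if positions else "-"


def write_reads(path: str | Path | TextIO, reads: Iterable[ReadRecord],
                reference_length: int) -> int:
    """Write records to MRF; returns the number of reads written."""
    if isinstance(path, (str, Path)):
        handle: TextIO = open(path, "wt", encoding="utf-8")
        own = True
    else:
        handle, own = path, False
    n = 0
    try:
        handle.write("#MRF\tv1\n")
        handle.write(f"#length\t{reference_length}\n")
        for r in reads:
            cov = ",".join(f"{a}-{b}" for a, b in r.covered)
            handle.write(f"{r.read_id}\tcov={cov}\tmut={_poslist_str(r.mutations)}"
                         f"\tlowq={_poslist_str(r.lowq)}\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n


# ---------------------------------------------------------------------------
# Quality rule
# ---------------------------------------------------------------------------

def apply_quality_rule(read: ReadRecord) -> ReadRecord:
    """Drop low-quality positions from a record.

    Only bases above the phred cutoff count: low-quality positions are removed
    from the covered intervals (splitting them where needed) and mutations at
    those positions are discarded.  The returned record has an empty ``lowq``
    set; the operation is idempotent.
    """
    if not read.lowq:
        return read
    intervals: list[tuple[int, int]] = []
    drop = sorted(read.lowq)
    for a, b in read.covered:
        start = a
        for p in drop:
            if p < start:
                continue
            if p > b:
                break
            if p > start:
                intervals.append((start, p - 1))
            start = p + 1
        if start <= b:
            intervals.append((start, b))
    return replace(
        read,
        covered=tuple(intervals),
        mutations=read.mutations - read.lowq,
        lowq=frozenset(),
    )


# ---------------------------------------------------------------------------
# Masks and reference
# ---------------------------------------------------------------------------

def load_mask(path: str | Path) -> PositionMask:
    """Load a position mask: one 1-based integer per line, '#' comments allowed."""
    excluded = set()
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                excluded.add(int(line))
            except ValueError:
                raise MRFFormatError(f"non-integer mask entry {line!r}", lineno)
    return PositionMask(frozenset(excluded))


def write_mask(path: str | Path, mask: PositionMask) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        for p in sorted(mask.excluded):
            handle.write(f"{p}\n")


def load_reference(path: str | Path) -> ReferenceSequence:
    """Load the first record of a FASTA file as the reference sequence."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA record in {path}")
    return ReferenceSequence(name=record.id, bases=str(record.seq).upper())


def reads_from_string(text: str, reference_length: int | None = None) -> list[ReadRecord]:
    """Parse MRF from a string; convenience for small in-memory inputs."""
    return list(parse_reads(io.StringIO(text), reference_length))
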