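"""Internal dense-boolean batch representation of reads.

Counting all i<j pairs per read naively is quadratic in covered length; the
accumulator instead works on chunks of reads held as boolean masks, from which
coverage intervals and mutation positions fall out as array transitions.  This
module is private; correctness is pinned to the brute-force per-read oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .reads_io import ReadRecord

DEFAULT_CHUNK = 4096


@dataclass
class ReadBatch:
    """A chunk of reads as dense boolean masks over 1..L (column p-1 = position p)."""

    cover: np.ndarray      # (n, L) bool
    mut: np.ndarray        # (n, L) bool, subset of cover
    lowq: np.ndarray       # (n, L) bool, subset of cover
    read_ids: list[str] | None = None

    @property
    def n_reads(self) -> int:
        return self.cover.shape[0]

    @property
    def length(self) -> int:
        return self.cover.shape[1]

    def apply_quality_rule(self) -> "ReadBatch":
        if not self.lowq.any():
            return self
        keep = ~self.lowq
        return ReadBatch(
            cover=self.cover & keep,
            mut=self.mut & keep,
            lowq=np.zeros_like(self.lowq),
            read_ids=self.read_ids,
        )

    def intervals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Maximal covered runs as (read_index, start, end), 1-based closed."""
        n, L = self.cover.shape
        padded = np.zeros((n, L + 2), dtype=np.int8)
        padded[:, 1:L + 1] = self.cover
        d = np.diff(padded, axis=1)
        r_start, c_start = np.nonzero(d == 1)
        r_end, c_end = np.nonzero(d == -1)
        # starts/ends appear in matching order within each row
        return r_start, c_start + 1, c_end  # end column index = position of last covered base

    def mutation_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Mutations as (read_index, 1-based position)."""
        r, c = np.nonzero(self.mut)
        return r, c + 1

    def to_records(self, id_prefix: str = "r", id_offset: int = 0) -> list[ReadRecord]:
        ri, a, b = self.intervals()
        rm, mp = self.mutation_positions()
        rq, qp = np.nonzero(self.lowq)
        qp = qp + 1
        n = self.n_reads
        ivs: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for k in range(len(ri)):
            ivs[ri[k]].append((int(a[k]), int(b[k])))
        muts: list[list[int]] = [[] for _ in range(n)]
        for k in range(len(rm)):
            muts[rm[k]].append(int(mp[k]))
        lowqs: list[list[int]] = [[] for _ in range(n)]
        for k in range(len(rq)):
            lowqs[rq[k]].append(int(qp[k]))
        out = []
        for i in range(n):
            rid = self.read_ids[i] if self.read_ids else f"{id_prefix}{id_offset + i}"
            out.append(ReadRecord(
                read_id=rid,
                covered=tuple(ivs[i]),
                mutations=frozenset(muts[i]),
                lowq=frozenset(lowqs[i]),
            ))
        return out


def records_to_batch(records: list[ReadRecord], length: int) -> ReadBatch:
    n = len(records)
    cover = np.zeros((n, length), dtype=bool)
    mut = np.zeros((n, length), dtype=bool)
    lowq = np.zeros((n, length), dtype=bool)
    ids = []
    for i, r in enumerate(records):
        ids.append(r.read_id)
        for a, b in r.covered:
            if b > length:
                raise ValueError(f"read {r.read_id!r} extends beyond reference length {length}")
            cover[i, a - 1:b] = True
        if r.mutations:
            mut[i, np.fromiter(r.mutations, dtype=np.int64) - 1] = True
        if r.lowq:
            lowq[i, np.fromiter(r.lowq, dtype=np.int64) - 1] = True
    return ReadBatch(cover=cover, mut=mut, lowq=lowq, read_ids=ids)


def as_batches(reads: Iterable[ReadRecord] | Iterable[ReadBatch], length: int,
               chunk: int = DEFAULT_CHUNK) -> Iterator[ReadBatch]:
    """Normalize a stream of ReadRecords (or ready-made batches) into batches."""
    buffer: list[ReadRecord] = []
    for item in reads:
        if isinstance(item, ReadBatch):
            if buffer:
                yield records_to_batch(buffer, length)
                buffer = []
            if item.length != length:
                raise ValueError(f"batch length {item.length} != reference length {length}")
            yield item
        else:
            buffer.append(item)
            if len(buffer) >= chunk:
                yield records_to_batch(buffer, length)
                buffer = []
    if buffer:
        yield records_to_batch(buffer, length)


def cartesian_pairs(values: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All ordered within-group pairs for groups of sizes ``counts`` laid out
    consecutively in ``values``; returns (left, right) arrays of total length
    sum(counts**2)."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() == 0:
        e = np.empty(0, dtype=values.dtype)
        return e, e.copy()
    left = np.repeat(values, np.repeat(counts, counts))
    sq = counts * counts
    total = int(sq.sum())
    idx = np.arange(total, dtype=np.int64)
    pair_off = np.concatenate(([0], np.cumsum(sq)[:-1]))
    val_off = np.concatenate(([0], np.cumsum(counts)[:-1]))
    gid = np.repeat(np.arange(len(counts)), sq)
    local = idx - pair_off[gid]
    right = values[val_off[gid] + (local % np.maximum(counts[gid], 1))]
    return left, right
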