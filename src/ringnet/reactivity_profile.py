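"""Per-nucleotide mutation-rate profiles and differential footprinting.

This is the conventional chemical-probing readout: for each position, the
fraction of quality-passing reads covering it that carry a mutation there.
Profiles from treated/untreated or ligand-plus/ligand-minus samples support
two derived analyses: masking positions with a high background mutation rate
(typically sequence polymorphisms) and calling localized reactivity changes
(footprints) between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._batch import ReadBatch, as_batches
from .reads_io import PositionMask, ReadRecord, ReferenceSequence

__all__ = [
    "ReactivityProfile",
    "FootprintCall",
    "compute_profile",
    "flag_high_background",
    "differential_footprint",
]


@dataclass
class ReactivityProfile:
    """Per-position depth, mutation count and mutation rate for one sample.

    ``rate`` is NaN at masked positions and positions never covered (missing,
    not zero).  Arrays are indexed 0..L-1 for positions 1..L.
    """

    depth: np.ndarray
    count: np.ndarray
    mask: PositionMask
    sample: str = ""
    bases: str | None = None

    def __post_init__(self):
        if self.depth.shape != self.count.shape:
            raise ValueError("depth and count shapes differ")
        if np.any(self.count > self.depth):
            raise ValueError("mutation count exceeds depth")

    @property
    def length(self) -> int:
        return len(self.depth)

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.depth > 0, self.count / np.maximum(self.depth, 1), np.nan)
        if len(self.mask):
            r = r.copy()
            r[np.fromiter(self.mask.excluded, dtype=np.int64) - 1] = np.nan
        return r

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(1, self.length + 1)
        masked = np.zeros(self.length, dtype=bool)
        if len(self.mask):
            masked[np.fromiter(self.mask.excluded, dtype=np.int64) - 1] = True
        return pd.DataFrame({
            "position": pos,
            "base": list(self.bases) if self.bases else ["N"] * self.length,
            "depth": self.depth,
            "mut_count": self.count,
            "rate": self.rate,
            "masked_flag": masked.astype(int),
        })

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"# sample={self.sample or 'unnamed'}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="nan")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReactivityProfile":
        sample = ""
        with open(path, "rt", encoding="utf-8") as fh:
            pos = fh.tell()
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("sample="):
                        sample = tok.removeprefix("sample=")
            else:
                fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        masked = frozenset(df.loc[df["masked_flag"] == 1, "position"].astype(int))
        bases = "".join(df["base"].astype(str)) if "base" in df else None
        return cls(depth=df["depth"].to_numpy(np.int64),
                   count=df["mut_count"].to_numpy(np.int64),
                   mask=PositionMask(masked), sample=sample, bases=bases)


@dataclass(frozen=True)
class FootprintCall:
    """A per-position reactivity difference between two conditions."""

    position: int
    rate_a: float
    rate_b: float
    delta: float
    z: float
    verdict: str  # protected | enhanced | unchanged


def compute_profile(reads: Iterable[ReadRecord] | Iterable[ReadBatch], length: int,
                    mask: PositionMask | None = None, sample: str = "",
                    reference: ReferenceSequence | None = None,
                    apply_quality: bool = True) -> ReactivityProfile:
    """Per-position mutation-rate profile from a read stream.

    Depth counts quality-passing coverage; low-quality bases are excluded from
    both depth and mutation count.
    """
    mask = mask if mask is not None else PositionMask.empty()
    depth = np.zeros(length, dtype=np.int64)
    count = np.zeros(length, dtype=np.int64)
    for batch in as_batches(reads, length):
        if apply_quality:
            batch = batch.apply_quality_rule()
        depth += batch.cover.sum(axis=0)
        count += batch.mut.sum(axis=0)
    return ReactivityProfile(depth=depth, count=count, mask=mask, sample=sample,
                             bases=reference.bases if reference else None)


def flag_high_background(untreated: ReactivityProfile, rate_cut: float = 0.03,
                         depth_min: int = 100) -> PositionMask:
    """Positions with a high mutation rate in an untreated (no-reagent) control.

    Such positions — mostly sequence polymorphisms relative to the reference —
    would contaminate every pair they enter and are excluded from all counting.
    Requires ``depth >= depth_min`` so a handful of noisy reads cannot flag a
    position.
    """
    rate = untreated.rate
    with np.errstate(invalid="ignore"):
        hot = (untreated.depth >= depth_min) & (np.nan_to_num(rate, nan=0.0) > rate_cut)
    return PositionMask(frozenset((np.nonzero(hot)[0] + 1).tolist()))


def differential_footprint(a: ReactivityProfile, b: ReactivityProfile,
                           z_min: float = 5.0, delta_min: float = 0.01,
                           full_table: bool = False):
    """Call per-position reactivity differences between two conditions.

    For each position, ``delta = rate_a - rate_b`` and a Poisson-approximation
    z-statistic ``z = delta / sqrt(rate_a/depth_a + rate_b/depth_b)``.  A
    position is "protected" (less reactive in *a*) when ``z <= -z_min`` and
    ``delta <= -delta_min``, "enhanced" when mirrored, else "unchanged".

    Returns only non-"unchanged" calls, or the full per-position table when
    ``full_table=True``.
    """
    if a.length != b.length:
        raise ValueError(f"profile lengths differ: {a.length} vs {b.length}")
    ra, rb = a.rate, b.rate
    valid = np.isfinite(ra) & np.isfinite(rb) & (a.depth > 0) & (b.depth > 0)
    delta = np.where(valid, ra - rb, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ra / np.maximum(a.depth, 1) + rb / np.maximum(b.depth, 1))
        z = np.where(valid & (se > 0), delta / np.where(se > 0, se, 1.0), 0.0)
        z = np.where(valid, z, np.nan)
    verdict = np.full(a.length, "unchanged", dtype=object)
    protected = valid & (z <= -z_min) & (delta <= -delta_min)
    enhanced = valid & (z >= z_min) & (delta >= delta_min)
    verdict[protected] = "protected"
    verdict[enhanced] = "enhanced"
    calls = [
        FootprintCall(position=int(p + 1), rate_a=float(ra[p]), rate_b=float(rb[p]),
                      delta=float(delta[p]), z=float(z[p]), verdict=str(verdict[p]))
        for p in np.nonzero(protected | enhanced)[0]
    ]
    if not full_table:
        return calls
    table = pd.DataFrame({
        "position": np.arange(1, a.length + 1),
        "rate_a": ra, "rate_b": rb, "delta": delta, "z": z, "verdict": verdict,
    })
    return calls, table
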