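"""Pairwise co-occurrence statistics over single-molecule mutation records.

For every nucleotide pair (i, j), i < j, a 2x2 contingency table counts the
joint mutation outcomes over all quality-passing reads that cover both
positions.  Because each pair's table is accumulated independently, memory
depends only on the RNA length, not the number of reads, and paired-end mates
separated by a gap still contribute every co-covered pair.

Significant correlations (RINGs — RNA interaction groups) are called with the
continuity-corrected (Yates) chi-squared statistic; correlation strength and
sign come from the phi coefficient, the Pearson correlation of the two binary
outcomes.  At the default criterion (chi2 > 20, 1 df) the probability that a
called pair is independent is below 1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._batch import ReadBatch, as_batches, cartesian_pairs
from .reads_io import PositionMask, ReadRecord

__all__ = [
    "ContingencyTable",
    "PairwiseAccumulator",
    "Ring",
    "RingSet",
    "DetectionInterval",
    "accumulate",
    "pair_depth",
    "yates_chi2",
    "phi_coeff",
    "detect_rings",
    "merge_replicates",
    "detection_interval",
]

RING_COLUMNS = ["i", "j", "n11", "n10", "n01", "n00", "depth", "chi2", "phi"]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint outcomes of (i mutated?, j mutated?) over reads covering both.

    ``n11``: both mutated; ``n10``: only i; ``n01``: only j; ``n00``: neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        """(R1, R2, C1, C2) = (i mutated, i unmutated, j mutated, j unmutated)."""
        return (self.n11 + self.n10, self.n01 + self.n00,
                self.n11 + self.n01, self.n10 + self.n00)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.n11, self.n01, self.n10, self.n00)


def yates_chi2(table: ContingencyTable) -> float:
    """Continuity-corrected chi-squared statistic for a 2x2 table.

    ``N * (max(0, |n11*n00 - n10*n01| - N/2))^2 / (R1*R2*C1*C2)``.

    The correction term is clamped at zero, so near-independent tables score
    exactly 0 rather than a spurious positive value.  Returns 0 when any
    marginal is zero (the statistic is undefined; no evidence either way).
    """
    N = table.total
    if N == 0:
        return 0.0
    r1, r2, c1, c2 = table.marginals
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    ad_bc = table.n11 * table.n00 - table.n10 * table.n01
    num = max(abs(ad_bc) - N / 2.0, 0.0)
    return N * num * num / denom


def phi_coeff(table: ContingencyTable) -> float:
    """Signed phi coefficient: Pearson correlation of the two binary outcomes.

    Positive phi means co-modification; negative phi means mutual exclusion.

    Raises
    ------
    ValueError
        If any marginal is zero (phi undefined).
    """
    r1, r2, c1, c2 = table.marginals
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        raise ValueError("phi undefined: a marginal of the table is zero")
    ad_bc = table.n11 * table.n00 - table.n10 * table.n01
    return ad_bc / math.sqrt(denom)


def _yates_chi2_arrays(n11, n10, n01, n00):
    n11 = n11.astype(np.float64); n10 = n10.astype(np.float64)
    n01 = n01.astype(np.float64); n00 = n00.astype(np.float64)
    N = n11 + n10 + n01 + n00
    r1, r2 = n11 + n10, n01 + n00
    c1, c2 = n11 + n01, n10 + n00
    denom = r1 * r2 * c1 * c2
    ad_bc = n11 * n00 - n10 * n01
    num = np.maximum(np.abs(ad_bc) - N / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, N * num * num / denom, 0.0)
        phi = np.where(denom > 0, ad_bc / np.sqrt(denom), np.nan)
    return chi2, phi


class PairwiseAccumulator:
    """Upper-triangular store of 2x2 contingency tables over all position pairs.

    Internally three full LxL count matrices are kept, from which any pair's
    table is reconstructed:

    - ``pair_cov[i, j]``: reads covering both i and j (= N_ij),
    - ``mut_cov[i, j]``: reads with i mutated and j covered (asymmetric),
    - ``mut_mut[i, j]``: reads with both i and j mutated.

    Updates are streamed per read chunk with difference arrays (coverage and
    mutation-times-interval rectangles), so per-read work is linear in the
    number of intervals and mutations rather than quadratic in covered length;
    explicit pair enumeration happens only for mutation-mutation pairs.
    Masked positions contribute to no table.
    """

    def __init__(self, length: int, mask: PositionMask | None = None,
                 min_separation: int = 1):
        if length < 1:
            raise ValueError("reference length must be >= 1")
        if min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        self.length = length
        self.mask = mask if mask is not None else PositionMask.empty()
        self.mask.validate(length)
        self.min_separation = min_separation
        self.n_reads = 0
        L = length
        self._cov_diff = np.zeros((L + 1) * (L + 1), dtype=np.int64)
        self._mutrow_diff = np.zeros(L * (L + 1), dtype=np.int64)
        self._mut_mut = np.zeros(L * L, dtype=np.int64)
        self._finalized = False
        self._pair_cov: np.ndarray | None = None
        self._mut_cov: np.ndarray | None = None

    # -- accumulation ------------------------------------------------------

    def add_batch(self, batch: ReadBatch) -> None:
        if self._finalized:
            raise RuntimeError("accumulator already finalized")
        if batch.length != self.length:
            raise ValueError("batch length does not match accumulator")
        L = self.length
        batch = batch.apply_quality_rule()
        self.n_reads += batch.n_reads

        ri, a, b = batch.intervals()          # 1-based closed intervals
        rm, mp = batch.mutation_positions()   # 1-based positions
        n = batch.n_reads
        iv_counts = np.bincount(ri, minlength=n)
        mut_counts = np.bincount(rm, minlength=n)

        # pair coverage: rectangle [a_u..b_u] x [a_v..b_v] for every ordered
        # interval pair (u, v) of the same read, via a 2-D difference array
        u, v = cartesian_pairs(np.arange(len(ri), dtype=np.int64), iv_counts)
        if len(u):
            a0u, b1u = a[u] - 1, b[u]          # rows [a0u, b1u)
            a0v, b1v = a[v] - 1, b[v]
            W = L + 1
            np.add.at(self._cov_diff, a0u * W + a0v, 1)
            np.add.at(self._cov_diff, a0u * W + b1v, -1)
            np.add.at(self._cov_diff, b1u * W + a0v, -1)
            np.add.at(self._cov_diff, b1u * W + b1v, 1)

        # (i mutated, j covered): row difference update per (mutation, interval)
        pm, iv = _cross_pairs(mp, mut_counts, np.arange(len(ri), dtype=np.int64), iv_counts)
        if len(pm):
            W = L + 1
            rows = (pm - 1) * W
            np.add.at(self._mutrow_diff, rows + (a[iv] - 1), 1)
            np.add.at(self._mutrow_diff, rows + b[iv], -1)

        # mutation-mutation pairs: explicit enumeration (few per read)
        p, q = cartesian_pairs(mp, mut_counts)
        if len(p):
            flat = (p - 1) * L + (q - 1)
            self._mut_mut += np.bincount(flat, minlength=L * L)

    def finalize(self) -> None:
        if self._finalized:
            return
        L = self.length
        W = L + 1
        cov = self._cov_diff.reshape(W, W).cumsum(axis=0).cumsum(axis=1)[:L, :L]
        mut_cov = self._mutrow_diff.reshape(L, W).cumsum(axis=1)[:, :L]
        mut_mut = self._mut_mut.reshape(L, L)
        if len(self.mask):
            idx = np.fromiter(self.mask.excluded, dtype=np.int64) - 1
            for m in (cov, mut_cov, mut_mut):
                m[idx, :] = 0
                m[:, idx] = 0
        self._pair_cov = cov
        self._mut_cov = mut_cov
        self._mut_mut = mut_mut.reshape(-1)
        self._finalized = True

    # -- access ------------------------------------------------------------

    def _require_final(self):
        if not self._finalized:
            self.finalize()

    def _check_pair(self, i: int, j: int) -> None:
        if not (1 <= i < j <= self.length):
            raise ValueError(f"need 1 <= i < j <= {self.length}, got ({i}, {j})")
        if i in self.mask or j in self.mask:
            raise ValueError(f"pair ({i}, {j}) involves a masked position")
        if j - i < self.min_separation:
            raise ValueError(f"pair ({i}, {j}) closer than min_separation="
                             f"{self.min_separation}")

    def table(self, i: int, j: int) -> ContingencyTable:
        """Contingency table for positions i < j."""
        self._require_final()
        self._check_pair(i, j)
        L = self.length
        n11 = int(self._mut_mut[(i - 1) * L + (j - 1)])
        r1 = int(self._mut_cov[i - 1, j - 1])
        c1 = int(self._mut_cov[j - 1, i - 1])
        N = int(self._pair_cov[i - 1, j - 1])
        return ContingencyTable(n11=n11, n10=r1 - n11, n01=c1 - n11,
                                n00=N - r1 - c1 + n11)

    def pair_depth(self, i: int, j: int) -> int:
        """N_ij: number of quality-passing reads covering both i and j."""
        self._require_final()
        self._check_pair(i, j)
        return int(self._pair_cov[i - 1, j - 1])

    def depth_matrix(self) -> np.ndarray:
        """Full symmetric LxL pair-coverage matrix (diagonal = single-position depth)."""
        self._require_final()
        return self._pair_cov.copy()

    def pair_arrays(self) -> dict[str, np.ndarray]:
        """All testable pairs (i < j, separation >= min_separation, unmasked)
        as flat arrays: i, j, n11, n10, n01, n00, depth."""
        self._require_final()
        L = self.length
        iu, ju = np.triu_indices(L, k=self.min_separation)
        if len(self.mask):
            masked = np.zeros(L, dtype=bool)
            masked[np.fromiter(self.mask.excluded, dtype=np.int64) - 1] = True
            keep = ~(masked[iu] | masked[ju])
            iu, ju = iu[keep], ju[keep]
        n11 = self._mut_mut.reshape(L, L)[iu, ju]
        r1 = self._mut_cov[iu, ju]
        c1 = self._mut_cov[ju, iu]
        N = self._pair_cov[iu, ju]
        return {
            "i": iu + 1, "j": ju + 1,
            "n11": n11, "n10": r1 - n11, "n01": c1 - n11,
            "n00": N - r1 - c1 + n11, "depth": N,
        }


def _cross_pairs(a_vals: np.ndarray, a_counts: np.ndarray,
                 b_vals: np.ndarray, b_counts: np.ndarray):
    """All ordered cross pairs (a, b) within each group; groups are aligned
    between the two (values laid out consecutively per group)."""
    a_counts = np.asarray(a_counts, dtype=np.int64)
    b_counts = np.asarray(b_counts, dtype=np.int64)
    if a_counts.sum() == 0 or b_counts.sum() == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    lens = np.repeat(b_counts, a_counts)           # per a-element: its group's b count
    left = np.repeat(a_vals, lens)
    total = int(lens.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    idx = np.arange(total, dtype=np.int64)
    off = np.concatenate(([0], np.cumsum(lens)[:-1]))
    eid = np.repeat(np.arange(len(lens)), lens)
    local = idx - off[eid]
    b_off = np.concatenate(([0], np.cumsum(b_counts)[:-1]))
    group_of_a = np.repeat(np.arange(len(a_counts)), a_counts)
    starts = b_off[group_of_a]                     # per a-element
    right = b_vals[starts[eid] + local]
    return left, right


def accumulate(reads: Iterable[ReadRecord] | Iterable[ReadBatch], length: int,
               mask: PositionMask | None = None, min_separation: int = 1,
               apply_quality: bool = True) -> PairwiseAccumulator:
    """Stream reads into a :class:`PairwiseAccumulator`.

    The per-base quality rule is (idempotently) applied unless
    ``apply_quality=False``.  Reads with disjoint covered intervals contribute
    only pairs where both positions are covered, so gaps between paired-end
    mates are handled naturally.
    """
    acc = PairwiseAccumulator(length, mask=mask, min_separation=min_separation)
    for batch in as_batches(reads, length):
        if not apply_quality:
            batch = ReadBatch(batch.cover, batch.mut,
                              np.zeros_like(batch.lowq), batch.read_ids)
        acc.add_batch(batch)
    acc.finalize()
    return acc


def pair_depth(acc: PairwiseAccumulator, i: int, j: int) -> int:
    """N_ij = sum of the four contingency-table cells for the pair."""
    return acc.pair_depth(i, j)


# ---------------------------------------------------------------------------
# RING detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ring:
    """One significant pairwise correlation between positions i < j."""

    i: int
    j: int
    table: ContingencyTable
    chi2: float
    phi: float

    @property
    def depth(self) -> int:
        return self.table.total


@dataclass
class RingSet:
    """Collection of detected rings with the thresholds that produced them.

    ``rings`` is a DataFrame with columns
    ``i, j, n11, n10, n01, n00, depth, chi2, phi`` sorted by (i, j).
    """

    rings: pd.DataFrame
    length: int
    provenance: str = ""
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.rings
        missing = [c for c in RING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ring table missing columns {missing}")
        if df.duplicated(subset=["i", "j"]).any():
            raise ValueError("duplicate (i, j) pairs in RingSet")
        self.rings = df[RING_COLUMNS].sort_values(["i", "j"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rings)

    def keys(self) -> set[tuple[int, int]]:
        return set(zip(self.rings["i"].astype(int), self.rings["j"].astype(int)))

    def __iter__(self):
        for row in self.rings.itertuples(index=False):
            yield Ring(
                i=int(row.i), j=int(row.j),
                table=ContingencyTable(int(row.n11), int(row.n10),
                                       int(row.n01), int(row.n00)),
                chi2=float(row.chi2), phi=float(row.phi),
            )

    def to_tsv(self, path: str | Path) -> None:
        """Write the correlations TSV (floats with 6 significant digits)."""
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"# length={self.length}")
            if self.provenance:
                fh.write(f" provenance={self.provenance}")
            for k, v in sorted(self.thresholds.items()):
                fh.write(f" {k}={v}")
            fh.write("\n")
            fh.write("\t".join(RING_COLUMNS) + "\n")
            for row in self.rings.itertuples(index=False):
                fh.write(f"{int(row.i)}\t{int(row.j)}\t{int(row.n11)}\t{int(row.n10)}"
                         f"\t{int(row.n01)}\t{int(row.n00)}\t{int(row.depth)}"
                         f"\t{row.chi2:.6g}\t{row.phi:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RingSet":
        length = 0
        provenance = ""
        thresholds: dict = {}
        with open(path, "rt", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "length":
                            length = int(v)
                        elif k == "provenance":
                            provenance = v
                        else:
                            try:
                                thresholds[k] = float(v)
                            except ValueError:
                                thresholds[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                df = pd.read_csv(path, sep="\t")
        if length == 0 and len(df):
            length = int(df["j"].max())
        return cls(rings=df, length=length, provenance=provenance,
                   thresholds=thresholds)


def detect_rings(acc: PairwiseAccumulator, chi2_min: float = 20.0,
                 depth_min: int = 10_000, provenance: str = "") -> RingSet:
    """Call significant correlated pairs (RINGs).

    A pair is reported when its pairwise depth N_ij >= ``depth_min`` and its
    Yates chi-squared statistic is strictly above ``chi2_min`` ("above 20"
    excludes the boundary).  Phi is attached signed: positive phi is
    co-modification, negative phi mutual exclusion.
    """
    arrays = acc.pair_arrays()
    chi2, phi = _yates_chi2_arrays(arrays["n11"], arrays["n10"],
                                   arrays["n01"], arrays["n00"])
    keep = (arrays["depth"] >= depth_min) & (chi2 > chi2_min) & np.isfinite(phi)
    df = pd.DataFrame({
        "i": arrays["i"][keep], "j": arrays["j"][keep],
        "n11": arrays["n11"][keep], "n10": arrays["n10"][keep],
        "n01": arrays["n01"][keep], "n00": arrays["n00"][keep],
        "depth": arrays["depth"][keep],
        "chi2": chi2[keep], "phi": phi[keep],
    })
    return RingSet(rings=df, length=acc.length, provenance=provenance,
                   thresholds={"chi2_min": chi2_min, "depth_min": depth_min,
                               "min_separation": acc.min_separation})


def merge_replicates(a: RingSet, b: RingSet) -> RingSet:
    """Pool two replicate ring sets by intersection.

    A pair is kept only if it was called in *both* replicates with the same
    phi sign.  Merged statistics are conservative and order-independent:
    phi = mean of the replicate phis, chi2 = min of the replicate chi2 values,
    depth and table cells = sums.
    """
    if a.length != b.length:
        raise ValueError(f"reference lengths differ: {a.length} vs {b.length}")
    m = a.rings.merge(b.rings, on=["i", "j"], suffixes=("_a", "_b"))
    same_sign = np.sign(m["phi_a"]) == np.sign(m["phi_b"])
    m = m[same_sign]
    df = pd.DataFrame({
        "i": m["i"], "j": m["j"],
        "n11": m["n11_a"] + m["n11_b"], "n10": m["n10_a"] + m["n10_b"],
        "n01": m["n01_a"] + m["n01_b"], "n00": m["n00_a"] + m["n00_b"],
        "depth": m["depth_a"] + m["depth_b"],
        "chi2": np.minimum(m["chi2_a"], m["chi2_b"]),
        "phi": (m["phi_a"] + m["phi_b"]) / 2.0,
    })
    prov = "+".join(p for p in (a.provenance, b.provenance) if p)
    thresholds = dict(a.thresholds)
    thresholds.update({f"rep_b_{k}": v for k, v in b.thresholds.items()
                       if a.thresholds.get(k) != v})
    thresholds["merge"] = "intersection,same-sign,mean-phi,min-chi2,sum-depth"
    return RingSet(rings=df, length=a.length, provenance=prov,
                   thresholds=thresholds)


# ---------------------------------------------------------------------------
# Detection interval
# ---------------------------------------------------------------------------

@dataclass
class DetectionInterval:
    """Maximum pair separation with adequate depth, plus per-separation summaries."""

    max_interval: int
    depth_required: int
    by_separation: pd.DataFrame  # separation, n_pairs, median_depth, max_depth


def detection_interval(acc: PairwiseAccumulator,
                       depth_required: int = 50_000) -> DetectionInterval:
    """Effective maximum detection interval.

    Roughly 50,000 reads spanning two positions are needed to reliably detect
    correlated modification, so the detection reach of a library is the
    largest separation j - i at which the pairwise depth still meets that
    threshold.  Returns 0 when no pair qualifies.
    """
    arrays = acc.pair_arrays()
    sep = arrays["j"] - arrays["i"]
    depth = arrays["depth"]
    qualifying = sep[depth >= depth_required]
    max_interval = int(qualifying.max()) if len(qualifying) else 0
    df = pd.DataFrame({"separation": sep, "depth": depth})
    summary = (df.groupby("separation")["depth"]
               .agg(n_pairs="size", median_depth="median", max_depth="max")
               .reset_index())
    return DetectionInterval(max_interval=max_interval,
                             depth_required=depth_required,
                             by_separation=summary)
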