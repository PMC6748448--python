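"""Latent-state read simulator with analytic ground truth.

The generator emulates a DMS-MaP experiment on a long RNA probed with randomly
primed, paired-end sequencing.  Correlated modification is produced by latent
binary factors ("blocks"): per molecule, each block's factor f_k is Bernoulli
with its occupancy p_k, and a member position i is chemically modified with
probability b_i + f_k * d_i (reactive A/C bases; G/U carry only a small
baseline).  Molecules therefore sample an ensemble of conformations, and
members of the same block co-modify, giving block-structured positive phi with
a closed form — the analytic oracle :func:`expected_phi`.

Sequencing is modelled as: fragment start uniform over the valid range, insert
length uniform on [insert_min, insert_max] (truncated at the RNA length), two
mates of fixed length at the fragment ends with a gap when the insert exceeds
twice the mate length, a symmetric background error folded in as
``observed = modified OR Bernoulli(e)``, and independent per-base low-quality
flags.  Output is byte-identical for a given scenario (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from ._batch import ReadBatch
from .reads_io import ReadRecord, ReferenceSequence, write_reads

__all__ = [
    "Block",
    "SimulationScenario",
    "GroundTruth",
    "simulate_batches",
    "simulate_reads",
    "simulate_to_mrf",
    "expected_phi",
    "ground_truth",
    "default_domain_scenario",
    "ligand_scenario",
    "null_scenario",
    "scenario_to_text",
]

_STRUCTURE_SEED = 161_542  # fixed: scenario structure is identical across read seeds

REACTIVE = frozenset("AC")


@dataclass(frozen=True)
class Block:
    """A latent binary factor and the positions it drives."""

    name: str
    positions: tuple[int, ...]          # 1-based, sorted, reactive bases
    occupancy: float                    # p_k, probability the factor is "on"
    increment: float                    # d_i added to each member's rate when on

    def __post_init__(self):
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError(f"block {self.name!r}: occupancy must be in (0, 1)")
        if self.increment < 0:
            raise ValueError(f"block {self.name!r}: increment must be >= 0")
        if tuple(sorted(set(self.positions))) != self.positions:
            raise ValueError(f"block {self.name!r}: positions must be sorted and unique")


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of one synthetic experiment."""

    length: int
    sequence: str
    blocks: tuple[Block, ...]
    base_rates: tuple[float, ...]       # b_i per position, 1..L
    seq_error: float = 0.001            # background error rate e (OR-folded)
    lowq_frac: float = 0.02             # per-base probability of a low-quality call
    n_fragments: int = 200_000
    insert_min: int = 500
    insert_max: int = 700
    mate_length: int = 150
    protection: tuple[int, float] | None = None     # (position, rate multiplier)
    coupling: tuple[str, str, float] | None = None  # (block_a, block_b, correlation)
    seed: int = 1
    name: str = "scenario"

    def __post_init__(self):
        if len(self.sequence) != self.length or len(self.base_rates) != self.length:
            raise ValueError("sequence and base_rates must have length L")
        if not 1 <= self.insert_min <= self.insert_max:
            raise ValueError("need 1 <= insert_min <= insert_max")
        if self.insert_min > self.length:
            raise ValueError("insert_min exceeds reference length")
        if not 0 <= self.seq_error < 1 or not 0 <= self.lowq_frac < 1:
            raise ValueError("seq_error and lowq_frac must be in [0, 1)")
        seen: set[int] = set()
        names = set()
        for blk in self.blocks:
            if blk.name in names:
                raise ValueError(f"duplicate block name {blk.name!r}")
            names.add(blk.name)
            for p in blk.positions:
                if not 1 <= p <= self.length:
                    raise ValueError(f"block position {p} outside 1..{self.length}")
                if self.sequence[p - 1] not in REACTIVE:
                    raise ValueError(f"block position {p} is not a reactive base (A/C)")
                if p in seen:
                    raise ValueError(f"position {p} belongs to more than one block")
                seen.add(p)
        b, d = self._rate_arrays()
        if np.any(b <= 0) or np.any(b + d >= 1):
            raise ValueError("need 0 < b_i and b_i + d_i < 1 at every position")
        if self.coupling is not None:
            a_name, b_name, rho = self.coupling
            if a_name not in names or b_name not in names or a_name == b_name:
                raise ValueError("coupling must name two distinct existing blocks")
            if not -1 < rho < 1:
                raise ValueError("coupling correlation must be in (-1, 1)")
        if self.protection is not None:
            pos, factor = self.protection
            if not 1 <= pos <= self.length:
                raise ValueError("protected position outside reference")
            if not 0 < factor <= 1:
                raise ValueError("protection factor must be in (0, 1]")

    # -- derived arrays ----------------------------------------------------

    def _rate_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(b, d): per-position base rate and latent increment, protection applied."""
        b = np.asarray(self.base_rates, dtype=np.float64).copy()
        d = np.zeros(self.length)
        for blk in self.blocks:
            idx = np.asarray(blk.positions, dtype=np.int64) - 1
            d[idx] = blk.increment
        if self.protection is not None:
            pos, factor = self.protection
            b[pos - 1] *= factor
            d[pos - 1] *= factor
        return b, d

    def block_of(self, pos: int) -> Block | None:
        for blk in self.blocks:
            if pos in blk.positions:
                return blk
        return None

    def reference(self) -> ReferenceSequence:
        return ReferenceSequence(name=self.name, bases=self.sequence)


@dataclass
class GroundTruth:
    """What the generator planted: block membership, expected per-position
    marginal rates (error-folded), and expected phi per planted pair."""

    membership: dict[int, str]
    expected_rate: np.ndarray
    pairs: pd.DataFrame  # i, j, expected_phi, block_i, block_j, kind

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("i\tj\texpected_phi\tblock_i\tblock_j\n")
            for row in self.pairs.itertuples(index=False):
                fh.write(f"{int(row.i)}\t{int(row.j)}\t{row.expected_phi:.6g}"
                         f"\t{row.block_i}\t{row.block_j}\n")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _coupled_pair_probs(pa: float, pb: float, rho: float) -> tuple[float, float]:
    """Conditional P(f_b = 1 | f_a) for a correlated Bernoulli pair."""
    p11 = pa * pb + rho * math.sqrt(pa * (1 - pa) * pb * (1 - pb))
    if not (max(0.0, pa + pb - 1) <= p11 <= min(pa, pb)):
        raise ValueError("requested factor correlation is infeasible for these occupancies")
    return p11 / pa, (pb - p11) / (1 - pa)


def simulate_batches(scenario: SimulationScenario,
                     chunk: int = 4096) -> Iterator[ReadBatch]:
    """Generate reads as dense boolean batches (the fast path).

    Fully reproducible from ``scenario.seed``: a single PCG64 stream drives
    factor draws, fragment geometry, modification, and quality flags in a
    fixed order.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.length
    b, d = scenario._rate_arrays()
    block_idx = [np.asarray(blk.positions, dtype=np.int64) - 1
                 for blk in scenario.blocks]
    occ = np.array([blk.occupancy for blk in scenario.blocks])
    coup = None
    if scenario.coupling is not None:
        names = [blk.name for blk in scenario.blocks]
        ia, ib = names.index(scenario.coupling[0]), names.index(scenario.coupling[1])
        coup = (ia, ib, _coupled_pair_probs(occ[ia], occ[ib], scenario.coupling[2]))
    pos = np.arange(1, L + 1)
    e = scenario.seq_error
    emitted = 0
    while emitted < scenario.n_fragments:
        m = min(chunk, scenario.n_fragments - emitted)
        # latent factors
        F = (rng.random((m, len(occ))) < occ[None, :]) if len(occ) else \
            np.zeros((m, 0), dtype=bool)
        if coup is not None:
            ia, ib, (p_b_given_a, p_b_given_not_a) = coup
            u = rng.random(m)
            F[:, ib] = np.where(F[:, ia], u < p_b_given_a, u < p_b_given_not_a)
        # fragment geometry
        insert = rng.integers(scenario.insert_min, scenario.insert_max + 1, size=m)
        insert = np.minimum(insert, L)
        start = 1 + (rng.random(m) * (L - insert + 1)).astype(np.int64)
        e1 = np.minimum(start + scenario.mate_length - 1, start + insert - 1)
        s2 = np.maximum(start + insert - scenario.mate_length, start)
        e2 = start + insert - 1
        cover = (((pos >= start[:, None]) & (pos <= e1[:, None]))
                 | ((pos >= s2[:, None]) & (pos <= e2[:, None])))
        # observed mutation: modified OR background error, one Bernoulli draw
        rate = np.broadcast_to(b, (m, L)).copy()
        for k, idx in enumerate(block_idx):
            rate[:, idx] += F[:, k:k + 1] * d[idx]
        p_obs = 1.0 - (1.0 - rate) * (1.0 - e)
        mut = (rng.random((m, L)) < p_obs) & cover
        if scenario.lowq_frac > 0:
            lowq = (rng.random((m, L)) < scenario.lowq_frac) & cover
        else:
            lowq = np.zeros((m, L), dtype=bool)
        ids = [f"sim{n}" for n in range(emitted, emitted + m)]
        yield ReadBatch(cover=cover, mut=mut, lowq=lowq, read_ids=ids)
        emitted += m


def simulate_reads(scenario: SimulationScenario
                   ) -> tuple[Iterator[ReadRecord], GroundTruth]:
    """Stream :class:`ReadRecord` objects plus the planted ground truth."""
    def _records() -> Iterator[ReadRecord]:
        for batch in simulate_batches(scenario):
            yield from batch.to_records()
    return _records(), ground_truth(scenario)


def simulate_to_mrf(scenario: SimulationScenario, path: str | Path) -> int:
    """Write the simulated reads to an MRF file; returns the read count."""
    records, _ = simulate_reads(scenario)
    return write_reads(path, records, scenario.length)


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------

def _folded_rate(r: np.ndarray | float, e: float):
    """Marginal observed rate after OR-folding the background error."""
    return r + e * (1.0 - r)


def expected_phi(scenario: SimulationScenario, i: int, j: int) -> float:
    """Closed-form expected phi between positions i and j.

    Within one block k: ``cov = p_k (1 - p_k) d_i d_j``.  Across two blocks
    coupled with factor correlation rho:
    ``cov = rho sqrt(p_a(1-p_a) p_b(1-p_b)) d_i d_j``.  Uncoupled cross-block
    or non-member pairs have phi 0.  The sequencing error shrinks the
    covariance by (1-e)^2 and inflates the marginals, so with folded marginal
    r' = r + e(1-r):

        phi = cov * (1-e)^2 / sqrt(r'_i (1-r'_i) r'_j (1-r'_j))
    """
    if i == j:
        raise ValueError("need two distinct positions")
    b, d = scenario._rate_arrays()
    blk_i, blk_j = scenario.block_of(i), scenario.block_of(j)
    if blk_i is None or blk_j is None:
        return 0.0
    if blk_i is blk_j:
        p = blk_i.occupancy
        cov_f = p * (1 - p)
    elif scenario.coupling is not None and \
            {blk_i.name, blk_j.name} == set(scenario.coupling[:2]):
        rho = scenario.coupling[2]
        pa, pb = blk_i.occupancy, blk_j.occupancy
        cov_f = rho * math.sqrt(pa * (1 - pa) * pb * (1 - pb))
    else:
        return 0.0
    di, dj = d[i - 1], d[j - 1]
    if di == 0.0 or dj == 0.0:
        return 0.0
    e = scenario.seq_error
    cov = cov_f * di * dj * (1 - e) ** 2
    ri = _folded_rate(b[i - 1] + blk_i.occupancy * di, e)
    rj = _folded_rate(b[j - 1] + blk_j.occupancy * dj, e)
    return cov / math.sqrt(ri * (1 - ri) * rj * (1 - rj))


def ground_truth(scenario: SimulationScenario) -> GroundTruth:
    """Planted membership, expected marginal rates, and expected phi for all
    within-block pairs (and coupled cross-block pairs when a coupling is set)."""
    b, d = scenario._rate_arrays()
    occ = np.zeros(scenario.length)
    membership: dict[int, str] = {}
    for blk in scenario.blocks:
        idx = np.asarray(blk.positions, dtype=np.int64) - 1
        occ[idx] = blk.occupancy
        for p in blk.positions:
            membership[p] = blk.name
    expected_rate = _folded_rate(b + occ * d, scenario.seq_error)
    rows = []
    for blk in scenario.blocks:
        ps = blk.positions
        for a_i in range(len(ps)):
            for b_i in range(a_i + 1, len(ps)):
                i, j = ps[a_i], ps[b_i]
                rows.append((i, j, expected_phi(scenario, i, j),
                             blk.name, blk.name, "within"))
    if scenario.coupling is not None:
        a_name, b_name, _ = scenario.coupling
        blk_a = next(blk for blk in scenario.blocks if blk.name == a_name)
        blk_b = next(blk for blk in scenario.blocks if blk.name == b_name)
        for i in blk_a.positions:
            for j in blk_b.positions:
                lo, hi = min(i, j), max(i, j)
                rows.append((lo, hi, expected_phi(scenario, lo, hi),
                             membership[lo], membership[hi], "coupled"))
    pairs = pd.DataFrame(rows, columns=["i", "j", "expected_phi",
                                        "block_i", "block_j", "kind"])
    pairs = pairs.sort_values(["i", "j"]).reset_index(drop=True)
    return GroundTruth(membership=membership, expected_rate=expected_rate,
                       pairs=pairs)


# ---------------------------------------------------------------------------
# Stock scenarios
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _reactive_positions(sequence: str, lo: int, hi: int) -> np.ndarray:
    return np.array([p for p in range(lo, hi + 1) if sequence[p - 1] in REACTIVE],
                    dtype=np.int64)


def _base_rate_array(rng: np.random.Generator, sequence: str,
                     lo: float = 0.01, hi: float = 0.05,
                     inert: float = 0.002) -> np.ndarray:
    """Reactive A/C bases draw b_i uniform on [lo, hi]; G/U are near-inert."""
    L = len(sequence)
    b = np.full(L, inert)
    reactive = np.array([c in REACTIVE for c in sequence])
    b[reactive] = rng.uniform(lo, hi, size=int(reactive.sum()))
    return b


def default_domain_scenario(seed: int = 1,
                            n_fragments: int = 200_000) -> SimulationScenario:
    """The stock four-domain scenario on a 1542-nt RNA.

    Four latent blocks mimic the domain layout of a small-subunit rRNA: body
    (within 1-560), platform (561-890), and two interleaved head blocks —
    outer-head in 930-1380, and inner-head+spine combining positions in
    930-1380 with a distal 1397-1535 stretch so that same-block pairs span
    several hundred nucleotides.  Each block has 40 reactive members with
    occupancy 0.5 and increment 0.3; base rates are 0.01-0.05 on A/C.  The
    scenario structure (sequence, members, rates) is fixed; only the read seed
    varies, so replicates share latent structure.
    """
    srng = np.random.default_rng(_STRUCTURE_SEED)
    L = 1542
    sequence = _random_sequence(srng, L)
    base_rates = _base_rate_array(srng, sequence)

    body = srng.choice(_reactive_positions(sequence, 1, 560), size=40, replace=False)
    platform = srng.choice(_reactive_positions(sequence, 561, 890), size=40,
                           replace=False)
    head = np.sort(srng.choice(_reactive_positions(sequence, 930, 1380), size=80,
                               replace=False))
    outer_head = head[0::2]                       # 40, interleaved with inner
    odd = head[1::2]                              # 24 of these, spread evenly
    inner_window = odd[np.round(np.linspace(0, len(odd) - 1, 24)).astype(int)]
    spine = srng.choice(_reactive_positions(sequence, 1397, 1535), size=16,
                        replace=False)
    inner_head = np.sort(np.concatenate([inner_window, spine]))

    def blk(name, positions):
        return Block(name=name, positions=tuple(int(p) for p in np.sort(positions)),
                     occupancy=0.5, increment=0.3)

    return SimulationScenario(
        length=L, sequence=sequence,
        blocks=(blk("body", body), blk("platform", platform),
                blk("outer-head", outer_head), blk("inner-head-spine", inner_head)),
        base_rates=tuple(base_rates),
        seq_error=0.001, lowq_frac=0.02,
        n_fragments=n_fragments, insert_min=500, insert_max=700, mate_length=150,
        seed=seed, name="default-domain",
    )


def ligand_scenario(seed: int = 1, n_fragments: int = 200_000,
                    protection_factor: float = 0.25,
                    coupling_rho: float = 0.8) -> SimulationScenario:
    """Ligand-bound variant of the stock scenario.

    Two effects of a bound small molecule: (i) protection — the focal binding
    site's modification rate is multiplied by ``protection_factor``; (ii)
    overstabilized long-range communication — the outer-head and
    inner-head+spine factors become correlated (joint occupancy correlation
    ``coupling_rho``), creating positive cross-block phi that is absent in the
    unliganded ensemble.  Marginal rates away from the focal site are
    unchanged, so the difference is invisible to per-nucleotide profiles.
    """
    base = default_domain_scenario(seed=seed, n_fragments=n_fragments)
    outer = next(blk for blk in base.blocks if blk.name == "outer-head")
    # focal site: the outer-head member closest to position 1192
    focal = min(outer.positions, key=lambda p: abs(p - 1192))
    return replace(base, protection=(int(focal), protection_factor),
                   coupling=("outer-head", "inner-head-spine", coupling_rho),
                   name="ligand")


def null_scenario(length: int = 200, n_fragments: int = 100_000,
                  seed: int = 1, lowq_frac: float = 0.0) -> SimulationScenario:
    """No latent structure: every position mutates independently.

    Reads cover the whole (short) reference so every pair reaches full depth;
    used to calibrate the false-positive rate of the significance criterion.
    """
    srng = np.random.default_rng(_STRUCTURE_SEED + 1)
    sequence = _random_sequence(srng, length)
    base_rates = _base_rate_array(srng, sequence)
    return SimulationScenario(
        length=length, sequence=sequence, blocks=(),
        base_rates=tuple(base_rates), seq_error=0.001, lowq_frac=lowq_frac,
        n_fragments=n_fragments, insert_min=length, insert_max=length,
        mate_length=length, seed=seed, name="null",
    )


def scenario_to_text(scenario: SimulationScenario) -> str:
    """Flat key: value echo of a scenario (sequence elided to its length)."""
    lines = [
        f"name: {scenario.name}",
        f"length: {scenario.length}",
        f"n_fragments: {scenario.n_fragments}",
        f"insert_min: {scenario.insert_min}",
        f"insert_max: {scenario.insert_max}",
        f"mate_length: {scenario.mate_length}",
        f"seq_error: {scenario.seq_error}",
        f"lowq_frac: {scenario.lowq_frac}",
        f"seed: {scenario.seed}",
        f"n_blocks: {len(scenario.blocks)}",
    ]
    for blk in scenario.blocks:
        lines.append(f"block.{blk.name}.occupancy: {blk.occupancy}")
        lines.append(f"block.{blk.name}.increment: {blk.increment}")
        lines.append(f"block.{blk.name}.positions: "
                     + ",".join(str(p) for p in blk.positions))
    if scenario.protection is not None:
        lines.append(f"protection.position: {scenario.protection[0]}")
        lines.append(f"protection.factor: {scenario.protection[1]}")
    if scenario.coupling is not None:
        lines.append(f"coupling.blocks: {scenario.coupling[0]},{scenario.coupling[1]}")
        lines.append(f"coupling.rho: {scenario.coupling[2]}")
    return "\n".join(lines) + "\n"
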