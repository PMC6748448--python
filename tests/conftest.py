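"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (per-read, per-pair loops; explicit
peeling) and independent of the package's vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ringnet.reads_io import ReadRecord
from ringnet import synthetic_data as sd
from ringnet.model import SingleMoleculeCorrelationModel


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_tables(reads, length, mask=frozenset(), min_separation=1):
    """Naive per-read, per-pair contingency count (independent quality rule)."""
    tables = {}
    for read in reads:
        covered = set()
        for a, b in read.covered:
            covered.update(range(a, b + 1))
        covered -= set(read.lowq)
        covered -= set(mask)
        muts = (set(read.mutations) - set(read.lowq)) & covered
        for i, j in itertools.combinations(sorted(covered), 2):
            if j - i < min_separation:
                continue
            key = (i, j)
            t = tables.setdefault(key, [0, 0, 0, 0])  # n11, n10, n01, n00
            mi, mj = i in muts, j in muts
            if mi and mj:
                t[0] += 1
            elif mi:
                t[1] += 1
            elif mj:
                t[2] += 1
            else:
                t[3] += 1
    return tables


def peel_kcore(edges, k):
    """Exhaustive iterative peeling: remove nodes with degree < k until stable."""
    edges = {frozenset(e) for e in edges}
    while True:
        degree = {}
        for e in edges:
            for n in e:
                degree[n] = degree.get(n, 0) + 1
        low = {n for n, d in degree.items() if d < k}
        if not low:
            return {n for e in edges for n in e}, edges
        edges = {e for e in edges if not (e & low)}
        if not edges:
            return set(), set()


def random_read(rng, length, max_intervals=2):
    """A random small ReadRecord over 1..length."""
    n_iv = rng.integers(1, max_intervals + 1)
    cuts = sorted(rng.choice(np.arange(1, length + 1), size=2 * n_iv,
                             replace=False))
    intervals = []
    for k in range(0, 2 * n_iv, 2):
        a, b = int(cuts[k]), int(cuts[k + 1])
        if intervals and a <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], b)
        else:
            intervals.append((a, b))
    covered = [p for a, b in intervals for p in range(a, b + 1)]
    n_mut = int(rng.integers(0, min(4, len(covered)) + 1))
    muts = frozenset(int(p) for p in rng.choice(covered, size=n_mut, replace=False))
    n_lowq = int(rng.integers(0, min(3, len(covered)) + 1))
    lowq = frozenset(int(p) for p in rng.choice(covered, size=n_lowq, replace=False))
    return ReadRecord(f"r{rng.integers(1e9)}", tuple(intervals), muts, lowq)


# ---------------------------------------------------------------------------
# Small hand fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def three_read_fixture():
    """Three full-coverage reads over 1..4 with mutation sets {1,3}, {1}, {}."""
    return [
        ReadRecord("a", ((1, 4),), frozenset({1, 3}), frozenset()),
        ReadRecord("b", ((1, 4),), frozenset({1}), frozenset()),
        ReadRecord("c", ((1, 4),), frozenset(), frozenset()),
    ]


# ---------------------------------------------------------------------------
# Session-scoped pipeline runs (shared by the expensive acceptance checks)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_replicate_fit():
    """One fitted replicate of the stock domain scenario, with ground truth."""
    scenario = sd.default_domain_scenario(seed=11)
    result = SingleMoleculeCorrelationModel.from_scenario(scenario).fit()
    return scenario, sd.ground_truth(scenario), result


@pytest.fixture(scope="session")
def small_domain_pair():
    """Two scaled-down replicates of the domain scenario (for fast end-to-end
    checks that do not need full depth)."""
    fits = []
    for seed in (21, 22):
        scen = sd.default_domain_scenario(seed=seed, n_fragments=40_000)
        fits.append(SingleMoleculeCorrelationModel.from_scenario(scen)
                    .fit(depth_min=1_000))
    truth = sd.ground_truth(sd.default_domain_scenario(seed=21))
    return fits[0], fits[1], truth
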