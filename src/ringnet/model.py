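"""Model/results interface over the correlated-probing pipeline.

`SingleMoleculeCorrelationModel` holds one sample's reads and configuration;
``fit()`` runs accumulation and significance testing and returns a
:class:`RingResults` carrying the called correlations, the per-nucleotide
reactivity profile, diagnostics, and a text summary.  Replicate merging,
network construction, and plotting hang off the results object.

Example
-------
>>> from ringnet import synthetic_data as sd
>>> from ringnet.model import SingleMoleculeCorrelationModel
>>> scen = sd.default_domain_scenario(seed=1, n_fragments=20_000)
>>> model = SingleMoleculeCorrelationModel.from_scenario(scen)
>>> res = model.fit(chi2_min=20, depth_min=500)
>>> len(res.rings) > 0
True
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import network_analysis as na
from . import pairwise_correlation as pc
from . import reactivity_profile as rp
from .reads_io import PositionMask, ReadRecord, parse_reads
from ._batch import ReadBatch

__all__ = ["SingleMoleculeCorrelationModel", "RingResults", "NetworkResults"]


class SingleMoleculeCorrelationModel:
    """Per-pair independence tests over single-molecule mutation records.

    Parameters
    ----------
    reads : iterable of ReadRecord (or internal batches)
        The sample's quality-annotated reads.  Consumed once, at ``fit``.
    length : int
        Reference length L.
    mask : PositionMask, optional
        Positions excluded from all counting.
    min_separation : int
        Minimum pair separation |i - j| to test (1 = all pairs).
    sample : str
        Label carried into outputs.
    """

    def __init__(self, reads: Iterable[ReadRecord] | Iterable[ReadBatch],
                 length: int, mask: PositionMask | None = None,
                 min_separation: int = 1, sample: str = ""):
        self.reads = reads
        self.length = length
        self.mask = mask if mask is not None else PositionMask.empty()
        self.min_separation = min_separation
        self.sample = sample

    @classmethod
    def from_mrf(cls, path: str | Path, length: int | None = None,
                 mask: PositionMask | None = None, min_separation: int = 1,
                 sample: str = "") -> "SingleMoleculeCorrelationModel":
        """Build from an MRF file (length read from the '#length' header if
        not given)."""
        if length is None:
            with open(path, "rt", encoding="utf-8") as fh:
                for line in fh:
                    if line.startswith("#length\t"):
                        length = int(line.split("\t")[1])
                        break
                    if not line.startswith("#"):
                        break
            if length is None:
                raise ValueError(f"{path}: no '#length' header; pass length=")
        return cls(parse_reads(path, length), length, mask=mask,
                   min_separation=min_separation,
                   sample=sample or Path(path).stem)

    @classmethod
    def from_scenario(cls, scenario, mask: PositionMask | None = None,
                      min_separation: int = 1) -> "SingleMoleculeCorrelationModel":
        """Build directly from a :mod:`ringnet.synthetic_data` scenario
        (fast path: no MRF round-trip)."""
        from .synthetic_data import simulate_batches
        return cls(simulate_batches(scenario), scenario.length, mask=mask,
                   min_separation=min_separation, sample=scenario.name)

    def fit(self, chi2_min: float = 20.0, depth_min: int = 10_000) -> "RingResults":
        """Accumulate contingency tables and call significant pairs.

        The per-base quality rule is applied; pairs with depth >=
        ``depth_min`` and Yates chi-squared strictly above ``chi2_min`` are
        reported as rings.
        """
        acc = pc.PairwiseAccumulator(self.length, mask=self.mask,
                                     min_separation=self.min_separation)
        depth = np.zeros(self.length, dtype=np.int64)
        count = np.zeros(self.length, dtype=np.int64)
        from ._batch import as_batches
        for batch in as_batches(self.reads, self.length):
            batch = batch.apply_quality_rule()
            acc.add_batch(batch)
            depth += batch.cover.sum(axis=0)
            count += batch.mut.sum(axis=0)
        acc.finalize()
        profile = rp.ReactivityProfile(depth=depth, count=count, mask=self.mask,
                                       sample=self.sample)
        ringset = pc.detect_rings(acc, chi2_min=chi2_min, depth_min=depth_min,
                                  provenance=self.sample)
        return RingResults(model=self, ringset=ringset, profile=profile,
                           accumulator=acc)


@dataclass
class RingResults:
    """Fitted results: called rings, reactivity profile, and diagnostics."""

    model: SingleMoleculeCorrelationModel | None
    ringset: pc.RingSet
    profile: rp.ReactivityProfile | None = None
    accumulator: pc.PairwiseAccumulator | None = None

    @property
    def rings(self) -> pd.DataFrame:
        return self.ringset.rings

    def merge(self, other: "RingResults") -> "RingResults":
        """Replicate-intersection merge (both replicates, same phi sign)."""
        merged = pc.merge_replicates(self.ringset, other.ringset)
        return RingResults(model=None, ringset=merged, profile=None,
                           accumulator=None)

    def detection_interval(self, depth_required: int = 50_000) -> pc.DetectionInterval:
        if self.accumulator is None:
            raise ValueError("no accumulator available (merged results?)")
        return pc.detection_interval(self.accumulator, depth_required)

    def to_network(self, weight_min: float = 0.015, kcore_k: int = 3,
                   resolution: float = 1.0, seed: int = 0) -> "NetworkResults":
        """Build, filter, and partition the correlation network."""
        g = na.build_graph(self.ringset)
        filtered = na.filter_graph(g, weight_min=weight_min, kcore_k=kcore_k)
        partition = None
        if filtered.n_nodes:
            partition = na.detect_communities(filtered, resolution=resolution,
                                              seed=seed)
        return NetworkResults(unfiltered=g, network=filtered, partition=partition)

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        df = self.rings
        t = self.ringset.thresholds
        lines = [
            "Single-molecule correlated probing fit",
            "=" * 46,
            f"sample:            {self.ringset.provenance or '-'}",
            f"reference length:  {self.ringset.length}",
            f"thresholds:        " + ", ".join(f"{k}={v}" for k, v in sorted(
                t.items(), key=lambda kv: kv[0])),
            f"rings called:      {len(df)}",
        ]
        if len(df):
            pos = int((df["phi"] > 0).sum())
            lines += [
                f"  positive phi:    {pos}",
                f"  negative phi:    {len(df) - pos}",
                f"  median |phi|:    {df['phi'].abs().median():.4g}",
                f"  median depth:    {df['depth'].median():.4g}",
                f"  max separation:  {int((df['j'] - df['i']).max())}",
            ]
        if self.profile is not None:
            rate = self.profile.rate
            ok = np.isfinite(rate)
            lines += [
                f"profiled positions: {int(ok.sum())}",
                f"  median rate:      {np.nanmedian(rate):.4g}" if ok.any() else "",
            ]
        return "\n".join(l for l in lines if l)

    # -- plotting ----------------------------------------------------------

    def plot_depth_by_separation(self, depth_required: int = 50_000, ax=None):
        """Median pairwise depth versus separation, with the reliability
        threshold marked — the detection-interval diagnostic."""
        import matplotlib.pyplot as plt
        di = self.detection_interval(depth_required)
        if ax is None:
            _, ax = plt.subplots()
        s = di.by_separation
        ax.plot(s["separation"], s["median_depth"], lw=1)
        ax.axhline(depth_required, ls="--", color="crimson",
                   label=f"required depth {depth_required:,}")
        ax.set_xlabel("pair separation j - i (nt)")
        ax.set_ylabel("median pairwise depth N_ij")
        ax.legend()
        return ax

    def plot_profile(self, ax=None):
        """Per-nucleotide mutation-rate profile."""
        import matplotlib.pyplot as plt
        if self.profile is None:
            raise ValueError("no profile available")
        if ax is None:
            _, ax = plt.subplots()
        rate = self.profile.rate
        ax.bar(np.arange(1, len(rate) + 1), np.nan_to_num(rate), width=1.0)
        ax.set_xlabel("position")
        ax.set_ylabel("mutation rate")
        return ax


@dataclass
class NetworkResults:
    """Filtered correlation network with its community partition."""

    unfiltered: na.RingNetwork
    network: na.RingNetwork
    partition: na.CommunityPartition | None

    def community_sizes(self) -> list[int]:
        return self.partition.sizes() if self.partition else []

    def n_communities(self, min_size: int = 1) -> int:
        return sum(1 for s in self.community_sizes() if s >= min_size)

    def node_strengths(self) -> pd.DataFrame:
        return na.node_strengths(self.network)

    def edge_categories(self):
        return na.edge_categories(self.network)

    def summary(self) -> str:
        g = self.network
        lines = [
            "Correlation network",
            "=" * 46,
            f"filter:        weight > {g.weight_min}, k-core {g.kcore_k}",
            f"nodes/edges:   {g.n_nodes} / {g.n_edges}",
        ]
        if self.partition:
            lines += [
                f"communities:   {len(self.partition.sizes())} "
                f"(sizes {self.partition.sizes()})",
                f"modularity:    {self.partition.modularity:.4f} "
                f"(resolution {self.partition.resolution}, seed {self.partition.seed})",
            ]
        return "\n".join(lines)
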