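"""MicroDNA circle calling from chimeric junctions.

A circular template sequenced through its junction produces a *head-to-tail*
chimeric alignment: the read jumps from a downstream genomic position (donor)
back to an upstream one (acceptor) on the same chromosome and strand.  That
orientation is the signature of a circle and distinguishes it from linear
splicing (acceptor downstream of donor), inversions (strand switch) and
translocations (chromosome switch).

Candidates (one per supporting junction read, after read-id deduplication)
are clustered by single linkage with a small per-endpoint tolerance, merged
clusters become calls with support = cluster size, and calls are filtered by
minimum support and the microDNA length regime (< 2 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io import JunctionRecord

logger = logging.getLogger("microdna.calling")


@dataclass(frozen=True)
class MicroDNACall:
    """One called microDNA circle (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    support: int = 1
    call_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start >= end in call {self.call_id or self!r}")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CallerConfig:
    min_support: int = 2
    cluster_tolerance_bp: int = 5
    min_length: int = 50
    max_length: int = 2000  # microDNA regime: small circles under 2 kb

    def __post_init__(self) -> None:
        if min(self.min_support, self.cluster_tolerance_bp, self.min_length, self.max_length) <= 0:
            raise ValueError("all caller parameters must be positive")
        if not self.min_length < self.max_length:
            raise ValueError("min_length must be < max_length")


@dataclass
class CallStats:
    """Per-sample caller bookkeeping: what was kept and what was discarded."""

    n_junctions: int = 0
    n_duplicate_reads: int = 0
    n_interchromosomal: int = 0
    n_strand_discordant: int = 0
    n_linear_orientation: int = 0
    n_candidates: int = 0
    n_clusters: int = 0
    n_filtered_support: int = 0
    n_filtered_length: int = 0
    n_calls: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def junctions_to_candidates(
    junctions: Iterable[JunctionRecord], stats: CallStats | None = None
) -> list[MicroDNACall]:
    """Emit one unclustered candidate (support 1) per circle-compatible junction.

    A junction is circle-compatible iff both segments map to the same
    chromosome and strand and the acceptor lies upstream of the donor in
    genome coordinates (head-to-tail).  Duplicate read ids are collapsed
    first so each candidate reflects a unique fragment observation.
    """
    stats = stats if stats is not None else CallStats()
    seen_reads: set[str] = set()
    candidates: list[MicroDNACall] = []
    for j in junctions:
        stats.n_junctions += 1
        if j.read_id in seen_reads:
            stats.n_duplicate_reads += 1
            continue
        seen_reads.add(j.read_id)
        if j.chrom_donor != j.chrom_acceptor:
            stats.n_interchromosomal += 1
            continue
        if j.strand_donor != j.strand_acceptor:
            stats.n_strand_discordant += 1
            continue
        if not j.pos_acceptor < j.pos_donor:
            stats.n_linear_orientation += 1
            continue
        # 1-based [acceptor, donor] becomes 0-based half-open [acceptor-1, donor)
        candidates.append(
            MicroDNACall(
                chrom=j.chrom_donor,
                start=j.pos_acceptor - 1,
                end=j.pos_donor,
                strand=j.strand_donor,
                support=1,
            )
        )
    stats.n_candidates = len(candidates)
    if stats.n_interchromosomal or stats.n_strand_discordant or stats.n_linear_orientation:
        logger.debug(
            "discarded junctions: %d inter-chromosomal, %d strand-discordant, %d linear-orientation",
            stats.n_interchromosomal,
            stats.n_strand_discordant,
            stats.n_linear_orientation,
        )
    return candidates


def _weighted_median(values: Sequence[int], weights: Sequence[int]) -> int:
    """Lower weighted median: smallest v with cumulative weight >= half the total."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(weights)
    acc = 0
    for i in order:
        acc += weights[i]
        if 2 * acc >= total:
            return values[i]
    return values[order[-1]]  # unreachable for positive weights


def _single_linkage_components(
    cands: list[MicroDNACall], tol: int
) -> list[list[int]]:
    """Connected components of the graph with an edge whenever both the start
    and the end of two candidates differ by <= ``tol``.

    Uses union-find over a start-sorted sweep: any edge implies a start
    difference <= tol, so only nearby candidates in start order are compared.
    """
    n = len(cands)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    order = sorted(range(n), key=lambda i: cands[i].start)
    for ii, i in enumerate(order):
        ci = cands[i]
        for j in order[ii + 1 :]:
            cj = cands[j]
            if cj.start - ci.start > tol:
                break
            if abs(cj.end - ci.end) <= tol:
                union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def cluster_and_filter(
    candidates: Sequence[MicroDNACall],
    config: CallerConfig = CallerConfig(),
    stats: CallStats | None = None,
    sample_id: str = "",
) -> list[MicroDNACall]:
    """Cluster same-locus candidates and apply support/length filters.

    Clustering is single linkage per chromosome+strand with per-endpoint
    tolerance ``cluster_tolerance_bp``; each cluster becomes one call whose
    endpoints are support-weighted medians (ties break toward the smaller
    coordinate) and whose support is the summed candidate support.  Calls are
    then filtered by ``min_support`` and ``[min_length, max_length]`` and
    sorted by (chrom, start, end, strand) — deterministic and independent of
    input order.
    """
    stats = stats if stats is not None else CallStats()
    by_group: dict[tuple[str, str], list[MicroDNACall]] = {}
    for c in candidates:
        by_group.setdefault((c.chrom, c.strand), []).append(c)

    calls: list[MicroDNACall] = []
    for (chrom, strand), group in by_group.items():
        for comp in _single_linkage_components(group, config.cluster_tolerance_bp):
            members = [group[i] for i in comp]
            weights = [m.support for m in members]
            start = _weighted_median([m.start for m in members], weights)
            end = _weighted_median([m.end for m in members], weights)
            support = sum(weights)
            stats.n_clusters += 1
            if support < config.min_support:
                stats.n_filtered_support += 1
                continue
            length = end - start
            if not (config.min_length <= length <= config.max_length):
                stats.n_filtered_length += 1
                continue
            calls.append(
                MicroDNACall(chrom=chrom, start=start, end=end, strand=strand, support=support)
            )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand, c.support))
    prefix = f"{sample_id}_" if sample_id else ""
    calls = [
        replace(c, call_id=f"{prefix}circ{i:05d}") for i, c in enumerate(calls, start=1)
    ]
    stats.n_calls = len(calls)
    return calls


def call_sample(
    junctions: Iterable[JunctionRecord],
    config: CallerConfig = CallerConfig(),
    sample_id: str = "",
) -> tuple[list[MicroDNACall], CallStats]:
    """Full per-sample calling: candidates, clustering, filtering, with stats."""
    stats = CallStats()
    cands = junctions_to_candidates(junctions, stats)
    calls = cluster_and_filter(cands, config, stats, sample_id=sample_id)
    return calls, stats
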