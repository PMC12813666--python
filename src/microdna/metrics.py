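"""Per-sample and per-stage descriptive metrics.

Covers the cohort-description layer: unique-fragment and producing-gene
counts normalised per million mapped reads, fragment-length distribution
statistics (mean and histogram modes — microDNA lengths are characteristically
bimodal around ~150 and ~294 bp), and rank-based two-group comparisons
between disease stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .calling import MicroDNACall
from .io import SampleMeta

logger = logging.getLogger("microdna.metrics")


def normalize_per_million(count: int, mapped_reads: int) -> float:
    """Counts per million mapped reads."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    return 1e6 * count / mapped_reads


def length_stats(
    calls: Sequence[MicroDNACall] | Sequence[int], histogram_bin_bp: int = 10
) -> tuple[float | None, list[float]]:
    """Mean fragment length and histogram modes.

    Modes are the centres of fixed-width histogram bins that strictly exceed
    both neighbouring bins, returned in descending height order.  An empty
    input yields ``(None, [])`` — the mean is missing, not zero.
    """
    if histogram_bin_bp < 1:
        raise ValueError("histogram_bin_bp must be >= 1")
    lengths = np.asarray(
        [c.length if isinstance(c, MicroDNACall) else int(c) for c in calls], dtype=float
    )
    if lengths.size == 0:
        return None, []
    mean = float(lengths.mean())
    lo = 0
    hi = int(np.ceil((lengths.max() + 1) / histogram_bin_bp)) * histogram_bin_bp
    edges = np.arange(lo, hi + histogram_bin_bp, histogram_bin_bp)
    hist, _ = np.histogram(lengths, bins=edges)
    modes: list[tuple[int, float]] = []
    for i in range(1, len(hist) - 1):
        if hist[i] > hist[i - 1] and hist[i] > hist[i + 1]:
            modes.append((int(hist[i]), float(edges[i] + histogram_bin_bp / 2)))
    if len(hist) >= 2:  # boundary bins count if they dominate their single neighbour
        if hist[0] > hist[1]:
            modes.append((int(hist[0]), float(edges[0] + histogram_bin_bp / 2)))
        if hist[-1] > hist[-2]:
            modes.append((int(hist[-1]), float(edges[-2] + histogram_bin_bp / 2)))
    elif len(hist) == 1:
        modes.append((int(hist[0]), float(edges[0] + histogram_bin_bp / 2)))
    modes.sort(key=lambda t: (-t[0], t[1]))
    return mean, [m for _, m in modes]


@dataclass
class SampleProfile:
    """Descriptive metrics for one sample's called microDNA."""

    sample_meta: SampleMeta
    calls: list[MicroDNACall]
    gene_of_call: dict[str, str | None] = field(default_factory=dict)  # call_id -> gene

    @property
    def n_fragments(self) -> int:
        return len(self.calls)

    @property
    def genes(self) -> set[str]:
        return {g for g in self.gene_of_call.values() if g is not None}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def fragments_per_million(self) -> float:
        return normalize_per_million(self.n_fragments, self.sample_meta.mapped_reads)

    @property
    def genes_per_million(self) -> float:
        return normalize_per_million(self.n_genes, self.sample_meta.mapped_reads)

    def length_summary(self, histogram_bin_bp: int = 10):
        return length_stats(self.calls, histogram_bin_bp)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Mann–Whitney rank-sum p-value: exact for both groups <= 10 (no ties),
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


METRICS = ("fragments_per_million", "genes_per_million", "n_fragments", "n_genes")


def stage_comparison(
    profiles: Sequence[SampleProfile], metric: str = "fragments_per_million"
) -> dict:
    """Per-stage summaries of a metric plus pairwise two-sided rank-sum p-values.

    Stages with zero samples are excluded (with a warning).  Mirrors the
    standard between-stage Mann–Whitney comparisons of cohort descriptives.
    """
    values: dict[str, list[float]] = {}
    for p in profiles:
        values.setdefault(p.sample_meta.stage, []).append(float(getattr(p, metric)))
    empty = [s for s, v in values.items() if not v]
    for s in empty:
        logger.warning("stage %s has no samples; excluded from comparison", s)
        del values[s]
    if len(values) < 2:
        raise ValueError("need >= 2 non-empty stages to compare")
    summary = {
        stage: {
            "n": len(v),
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
        }
        for stage, v in values.items()
    }
    stages = sorted(values)
    pvalues = {
        (a, b): rank_sum_test(values[a], values[b])
        for i, a in enumerate(stages)
        for b in stages[i + 1 :]
    }
    return {"metric": metric, "per_stage": summary, "pairwise_p": pvalues}
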