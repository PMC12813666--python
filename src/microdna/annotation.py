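"""Genomic-feature annotation of microDNA calls.

Each call is assigned to at most one gene (largest overlap with the gene's
transcription span extended by a 2 kb strand-aware promoter window) and to
exactly one feature category with precedence

    5'UTR/promoter  >  3'UTR  >  exon  >  intron

so that per-gene category counts partition the fragment total, as in
tabulated per-gene summaries where the category percentages sum to 100.
Open-chromatin overlap (DNase/ATAC peak sets, e.g. a lymphoblastoid cell
line and B-cell ALL) is flagged independently per named peak set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .calling import MicroDNACall
from .io import GeneModel, SampleMeta

CATEGORIES = ("exon", "utr5_promoter", "utr3", "intron")
DEFAULT_PROMOTER_BP = 2000


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FeatureAnnotation:
    call_id: str
    gene_name: str | None
    category: str  # exon | utr5_promoter | utr3 | intron | intergenic
    open_chromatin_flags: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if (self.gene_name is None) != (self.category == "intergenic"):
            raise ValueError("category is intergenic iff gene_name is None")

    @property
    def flags(self) -> dict[str, bool]:
        return dict(self.open_chromatin_flags)


class GeneIndex:
    """Interval index over promoter-extended gene spans for overlap queries."""

    def __init__(self, genes: Sequence[GeneModel], promoter_bp: int = DEFAULT_PROMOTER_BP):
        self.promoter_bp = promoter_bp
        self.by_name = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_name in self.by_name:
                raise ValueError(f"duplicate gene name {g.gene_name!r}")
            self.by_name[g.gene_name] = g
            lo, hi = self.extended_span(g)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    def extended_span(self, g: GeneModel) -> tuple[int, int]:
        pw = g.promoter_window(self.promoter_bp)
        return min(g.tx_start, pw[0]), max(g.tx_end, pw[1])

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_gene(
    call: MicroDNACall, index: GeneIndex
) -> str | None:
    """Assign a call to the gene whose promoter-extended span it overlaps most.

    Ties break to the lexicographically smallest gene name; no overlap at all
    returns ``None`` (intergenic).
    """
    best: tuple[int, str] | None = None
    for g in index.overlapping(call.chrom, call.start, call.end):
        lo, hi = index.extended_span(g)
        overlap = min(call.end, hi) - max(call.start, lo)
        if overlap <= 0:
            continue
        key = (-overlap, g.gene_name)
        if best is None or key < best:
            best = key
    return best[1] if best is not None else None


def _utr_intervals(gene: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic intervals upstream (5'UTR) and downstream (3'UTR) of the CDS."""
    if not gene.coding:
        return [], []
    left, right = [], []  # exonic sequence left/right of the CDS in genome coords
    for s, e in zip(gene.exon_starts, gene.exon_ends):
        if s < gene.cds_start:
            left.append((s, min(e, gene.cds_start)))
        if e > gene.cds_end:
            right.append((max(s, gene.cds_end), e))
    if gene.strand == "+":
        return left, right
    return right, left


def _overlaps_any(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(min(end, e) - max(start, s) > 0 for s, e in intervals)


def classify_feature(
    call: MicroDNACall, gene: GeneModel, promoter_bp: int = DEFAULT_PROMOTER_BP
) -> str:
    """Classify a gene-assigned call into exactly one feature category.

    Precedence: 5'UTR/promoter > 3'UTR > exon > intron.  The promoter window
    (``promoter_bp`` upstream of the strand-aware TSS) is pooled with the
    5'UTR; UTRs are derived from the exon/CDS structure; intron is the
    remainder of the transcription span.  Non-coding genes have no UTRs, so
    any exonic overlap classes as exon while the promoter window still
    applies.
    """
    utr5, utr3 = _utr_intervals(gene)
    utr5 = list(utr5) + [gene.promoter_window(promoter_bp)]
    if _overlaps_any(call.start, call.end, utr5):
        return "utr5_promoter"
    if _overlaps_any(call.start, call.end, utr3):
        return "utr3"
    exons = list(zip(gene.exon_starts, gene.exon_ends))
    if _overlaps_any(call.start, call.end, exons):
        return "exon"
    if min(call.end, gene.tx_end) - max(call.start, gene.tx_start) > 0:
        return "intron"
    raise RuntimeError(
        f"call {call.call_id} assigned to {gene.gene_name} but overlaps no feature"
    )


class PeakIndex:
    """Named open-chromatin peak sets indexed for half-open overlap queries."""

    def __init__(self, peak_sets: Mapping[str, Sequence[tuple[str, int, int]]]):
        self.names = tuple(peak_sets)
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for name, peaks in peak_sets.items():
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in peaks:
                if not start < end:
                    raise ValueError(f"invalid peak {chrom}:{start}-{end} in set {name}")
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees[name] = trees

    def flags_for(self, chrom: str, start: int, end: int) -> tuple[tuple[str, bool], ...]:
        out = []
        for name in self.names:
            tree = self._trees[name].get(chrom)
            out.append((name, bool(tree.overlap(start, end)) if tree is not None else False))
        return tuple(out)


def overlap_open_chromatin(
    calls: Sequence[MicroDNACall], peak_index: PeakIndex
) -> list[tuple[tuple[str, bool], ...]]:
    """Per-call boolean overlap flags (>= 1 shared base) per named peak set."""
    return [peak_index.flags_for(c.chrom, c.start, c.end) for c in calls]


def annotate_calls(
    calls: Sequence[MicroDNACall],
    genes: Sequence[GeneModel] | GeneIndex,
    peak_index: PeakIndex | None = None,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> list[FeatureAnnotation]:
    """Assign every call a gene (or intergenic) and one feature category."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_bp)
    annotations = []
    for call in calls:
        gene_name = assign_gene(call, index)
        if gene_name is None:
            category = "intergenic"
        else:
            category = classify_feature(call, index.by_name[gene_name], index.promoter_bp)
        flags = (
            peak_index.flags_for(call.chrom, call.start, call.end)
            if peak_index is not None
            else ()
        )
        annotations.append(
            FeatureAnnotation(
                call_id=call.call_id,
                gene_name=gene_name,
                category=category,
                open_chromatin_flags=flags,
            )
        )
    return annotations


@dataclass
class GeneAnnotationSummary:
    """Per-gene, per-tissue fragment characteristics (one row per gene/tissue)."""

    gene_name: str
    tissue: str
    n_individuals_dx: int
    n_individuals_rel: int
    n_microdna: int
    category_counts: dict[str, int]
    category_pct: dict[str, int]
    open_chromatin_counts: dict[str, int]
    open_chromatin_pct: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.n_microdna:
            raise ValueError("category counts must sum to n_microdna")


def summarize_gene(
    annotated: Sequence[tuple[FeatureAnnotation, str]],
    sample_meta: Mapping[str, SampleMeta],
) -> list[GeneAnnotationSummary]:
    """Aggregate (annotation, sample_id) pairs into per-gene/tissue summaries.

    Counts distinct patients with >= 1 fragment of the gene at diagnosis and
    at relapse, total fragments, per-category and per-peak-set counts with
    percentages rounded to the nearest integer (halves away from zero).
    Genes with zero fragments yield no row; intergenic fragments are ignored.
    """
    groups: dict[tuple[str, str], list[tuple[FeatureAnnotation, SampleMeta]]] = {}
    for ann, sid in annotated:
        if ann.gene_name is None:
            continue
        meta = sample_meta[sid]
        groups.setdefault((ann.gene_name, meta.tissue), []).append((ann, meta))

    summaries = []
    for (gene_name, tissue), items in sorted(groups.items()):
        n = len(items)
        cat_counts = {c: 0 for c in CATEGORIES}
        oc_counts: dict[str, int] = {}
        dx_patients, rel_patients = set(), set()
        for ann, meta in items:
            cat_counts[ann.category] += 1
            for name, flag in ann.open_chromatin_flags:
                oc_counts.setdefault(name, 0)
                if flag:
                    oc_counts[name] += 1
            if meta.stage == "diagnosis":
                dx_patients.add(meta.patient_id)
            elif meta.stage == "relapse":
                rel_patients.add(meta.patient_id)
        summaries.append(
            GeneAnnotationSummary(
                gene_name=gene_name,
                tissue=tissue,
                n_individuals_dx=len(dx_patients),
                n_individuals_rel=len(rel_patients),
                n_microdna=n,
                category_counts=cat_counts,
                category_pct={c: round_half_up(100 * k / n) for c, k in cat_counts.items()},
                open_chromatin_counts=oc_counts,
                open_chromatin_pct={
                    s: round_half_up(100 * k / n) for s, k in oc_counts.items()
                },
            )
        )
    return summaries
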