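import numpy as np
import pytest

from microdna import (
    GeneIndex,
    GeneModel,
    PeakIndex,
    annotate_calls,
    assign_gene,
    classify_feature,
    overlap_open_chromatin,
    summarize_gene,
)
from microdna.annotation import round_half_up

from conftest import make_call, plasma_meta


def build_aass_fixture():
    """42 plasma fragments partitioned 8 exon / 2 5'UTR-promoter / 1 3'UTR /
    31 intron across 5 diagnosis + 5 relapse individuals."""
    gene = GeneModel(
        gene_name="AASS", chrom="chr7", strand="+",
        tx_start=10_000, tx_end=40_000, cds_start=12_000, cds_end=38_000,
        exon_starts=(10_000, 20_000, 37_500), exon_ends=(12_500, 21_000, 40_000),
    )
    calls = (
        [make_call("chr7", 12_100, 12_200) for _ in range(8)]  # coding exon
        + [make_call("chr7", 10_500, 10_600) for _ in range(2)]  # 5'UTR
        + [make_call("chr7", 38_500, 38_600)]  # 3'UTR
        + [make_call("chr7", 15_000, 15_100) for _ in range(31)]  # intron
    )
    calls = [
        make_call(c.chrom, c.start, c.end, call_id=f"aass{i}")
        for i, c in enumerate(calls)
    ]
    meta = {}
    for i, pid in enumerate(["P1", "P2", "P3", "P4", "P5"]):
        for stage in ("diagnosis", "relapse"):
            m = plasma_meta(pid, stage)
            meta[m.sample_id] = m
    sample_ids = list(meta)
    assignment = [sample_ids[i % len(sample_ids)] for i in range(len(calls))]
    return gene, calls, assignment, meta


def build_kbtbd11_fixture():
    """39 plasma fragments on a minus-strand gene: 34 promoter/5'UTR, 1 exon,
    4 3'UTR; 35 overlap the LCL open-chromatin peak set."""
    gene = GeneModel(
        gene_name="KBTBD11", chrom="chr8", strand="-",
        tx_start=100_000, tx_end=130_000, cds_start=102_000, cds_end=128_000,
        exon_starts=(100_000, 119_000, 127_500), exon_ends=(102_500, 121_000, 130_000),
    )
    calls = (
        [make_call("chr8", 130_500, 130_600) for _ in range(20)]  # promoter (right side)
        + [make_call("chr8", 128_500, 128_600) for _ in range(14)]  # 5'UTR
        + [make_call("chr8", 120_000, 120_100)]  # coding exon
        + [make_call("chr8", 101_000, 101_100) for _ in range(4)]  # 3'UTR
    )
    calls = [
        make_call(c.chrom, c.start, c.end, call_id=f"kb{i}") for i, c in enumerate(calls)
    ]
    # LCL peaks cover the promoter/5'UTR block and the exonic call: 35 of 39
    peaks = {"LCL": [("chr8", 128_000, 132_000), ("chr8", 119_950, 120_050)]}
    return gene, calls, peaks


class TestAssignGene:
    def test_call_inside_exon_assigned(self, toy_plus_gene):
        index = GeneIndex([toy_plus_gene])
        assert assign_gene(make_call("chr7", 12_100, 12_200), index) == "AASS"

    def test_promoter_window_2kb_upstream_of_tss(self, toy_plus_gene):
        index = GeneIndex([toy_plus_gene])
        # 1,500 bp upstream of the + strand TSS: inside the 2 kb window
        assert assign_gene(make_call("chr7", 8_450, 8_550), index) == "AASS"
        # beyond 2 kb upstream: intergenic
        assert assign_gene(make_call("chr7", 7_500, 7_900), index) is None

    def test_largest_overlap_wins(self):
        a = GeneModel("geneA", "chr1", "+", 10_000, 20_000, 10_000, 20_000,
                      (10_000,), (20_000,))
        b = GeneModel("geneB", "chr1", "+", 19_920, 30_000, 19_920, 30_000,
                      (19_920,), (30_000,))
        index = GeneIndex([a, b], promoter_bp=0)
        # call [19880, 20080): 120 bp in geneA, 160 bp in geneB
        assert assign_gene(make_call("chr1", 19_880, 20_080), index) == "geneB"
        # call [19800, 20000): 200 bp in geneA, 80 bp in geneB
        assert assign_gene(make_call("chr1", 19_800, 20_000), index) == "geneA"

    def test_tie_breaks_lexicographically(self):
        a = GeneModel("geneB", "chr1", "+", 100, 200, 100, 200, (100,), (200,))
        b = GeneModel("geneA", "chr1", "+", 200, 300, 200, 300, (200,), (300,))
        index = GeneIndex([a, b], promoter_bp=0)
        assert assign_gene(make_call("chr1", 150, 250), index) == "geneA"


class TestClassifyFeature:
    def test_precedence_promoter_over_exon(self, toy_plus_gene):
        # spans the promoter boundary into the first exon
        call = make_call("chr7", 9_900, 10_100)
        assert classify_feature(call, toy_plus_gene) == "utr5_promoter"

    def test_intronic_call(self, toy_plus_gene):
        assert classify_feature(make_call("chr7", 15_000, 15_100), toy_plus_gene) == "intron"

    def test_utr3_on_plus_strand(self, toy_plus_gene):
        assert classify_feature(make_call("chr7", 38_500, 38_600), toy_plus_gene) == "utr3"

    def test_minus_strand_utr_orientation(self, toy_minus_gene):
        # high-coordinate exonic side is the 5'UTR on the minus strand
        assert classify_feature(make_call("chr8", 128_500, 128_600), toy_minus_gene) == "utr5_promoter"
        assert classify_feature(make_call("chr8", 101_000, 101_100), toy_minus_gene) == "utr3"
        # promoter extends rightward of tx_end
        assert classify_feature(make_call("chr8", 130_500, 130_600), toy_minus_gene) == "utr5_promoter"

    def test_noncoding_gene_exonic_call_is_exon(self):
        linc = GeneModel("LINC1", "chr1", "+", 1000, 5000, 1000, 1000,
                         (1000, 3000), (2000, 5000))
        assert classify_feature(make_call("chr1", 1200, 1300), linc) == "exon"
        assert classify_feature(make_call("chr1", 2200, 2300), linc) == "intron"


class TestOpenChromatin:
    def test_one_base_overlap_counts(self):
        idx = PeakIndex({"LCL": [("chr1", 250, 400)]})
        flags = overlap_open_chromatin([make_call("chr1", 100, 300)], idx)
        assert flags == [(("LCL", True),)]

    def test_half_open_boundary_no_shared_base(self):
        idx = PeakIndex({"LCL": [("chr1", 200, 300)]})
        flags = overlap_open_chromatin([make_call("chr1", 100, 200)], idx)
        assert flags == [(("LCL", False),)]

    def test_independent_flags_per_peak_set(self):
        idx = PeakIndex({"LCL": [("chr1", 0, 150)], "BALL": [("chr1", 500, 600)]})
        (flags,) = overlap_open_chromatin([make_call("chr1", 100, 300)], idx)
        assert dict(flags) == {"LCL": True, "BALL": False}


class TestPerGeneSummaries:
    def test_aass_like_category_percentages(self):
        gene, calls, assignment, meta = build_aass_fixture()
        annotations = annotate_calls(calls, [gene])
        summaries = summarize_gene(list(zip(annotations, assignment)), meta)
        (s,) = summaries
        assert s.n_microdna == 42
        assert s.category_counts == {"exon": 8, "utr5_promoter": 2, "utr3": 1, "intron": 31}
        assert s.category_pct == {"exon": 19, "utr5_promoter": 5, "utr3": 2, "intron": 74}
        assert s.n_individuals_dx == 5 and s.n_individuals_rel == 5
        assert sum(s.category_counts.values()) == s.n_microdna

    def test_kbtbd11_like_promoter_percentage_and_peaks(self):
        gene, calls, peaks = build_kbtbd11_fixture()
        annotations = annotate_calls(calls, [gene], PeakIndex(peaks))
        meta = {m.sample_id: m for m in [plasma_meta(f"P{i}", "diagnosis") for i in range(5)]}
        sample_ids = list(meta)
        assignment = [sample_ids[i % 5] for i in range(len(calls))]
        (s,) = summarize_gene(list(zip(annotations, assignment)), meta)
        assert s.n_microdna == 39
        assert s.category_counts["utr5_promoter"] == 34
        assert s.category_pct == {"exon": 3, "utr5_promoter": 87, "utr3": 10, "intron": 0}
        assert s.open_chromatin_counts == {"LCL": 35}
        assert s.open_chromatin_pct == {"LCL": 90}

    def test_percentage_rounding_slack(self):
        gene, calls, assignment, meta = build_aass_fixture()
        annotations = annotate_calls(calls, [gene])
        (s,) = summarize_gene(list(zip(annotations, assignment)), meta)
        assert 98 <= sum(s.category_pct.values()) <= 102

    def test_even_division_gives_exact_100(self):
        assert round_half_up(100 * 10 / 20) == 50
        gene = GeneModel("G", "chr1", "+", 1000, 5000, 1000, 1000, (1000,), (5000,))
        calls = [make_call("chr1", 1100, 1200, call_id=f"c{i}") for i in range(10)] + [
            make_call("chr1", 500, 600, call_id=f"p{i}") for i in range(10)
        ]
        annotations = annotate_calls(calls, [gene])
        meta = {plasma_meta("P1", "diagnosis").sample_id: plasma_meta("P1", "diagnosis")}
        (s,) = summarize_gene([(a, next(iter(meta))) for a in annotations], meta)
        assert sum(s.category_pct.values()) == 100

    def test_zero_call_gene_has_no_row(self):
        meta = {plasma_meta("P1", "diagnosis").sample_id: plasma_meta("P1", "diagnosis")}
        assert summarize_gene([], meta) == []

    def test_open_chromatin_fraction_direct_count(self, rng):
        gene = GeneModel("G", "chr1", "+", 0, 100_000, 0, 100_000, (0,), (100_000,))
        calls = [
            make_call("chr1", int(s), int(s) + 100, call_id=f"c{i}")
            for i, s in enumerate(range(0, 20_000, 1000))
        ]
        idx = PeakIndex({"LCL": [("chr1", 0, 9001)]})  # first 10 of 20 calls
        annotations = annotate_calls(calls, [gene], idx)
        meta = {plasma_meta("P1", "diagnosis").sample_id: plasma_meta("P1", "diagnosis")}
        (s,) = summarize_gene([(a, next(iter(meta))) for a in annotations], meta)
        assert s.open_chromatin_counts == {"LCL": 10}
        assert s.open_chromatin_pct == {"LCL": 50}


def test_interval_index_equals_brute_force_scan(rng):
    """Index-backed gene assignment agrees with an O(n*m) overlap scan."""
    genes = []
    for i in range(40):
        start = int(rng.integers(0, 500_000))
        length = int(rng.integers(2_000, 20_000))
        genes.append(
            GeneModel(f"G{i:02d}", "chr1", "+-"[int(rng.integers(2))],
                      start, start + length, start, start + length,
                      (start,), (start + length,))
        )
    index = GeneIndex(genes)
    for _ in range(200):
        s = int(rng.integers(0, 520_000))
        call = make_call("chr1", s, s + int(rng.integers(50, 2000)))
        best = None
        for g in genes:
            lo, hi = index.extended_span(g)
            ov = min(call.end, hi) - max(call.start, lo)
            if ov > 0 and (best is None or (-ov, g.gene_name) < best):
                best = (-ov, g.gene_name)
        assert assign_gene(call, index) == (best[1] if best else None)
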