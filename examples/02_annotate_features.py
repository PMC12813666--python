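"""Assign circles to genes and feature categories (promoter/UTR/exon/intron).

Each call gets the gene whose promoter-extended span it overlaps most, and
exactly one category with precedence 5'UTR/promoter > 3'UTR > exon > intron,
so per-gene category counts partition the fragment total.
"""

from microdna import (
    GeneModel,
    MicroDNACall,
    PeakIndex,
    annotate_calls,
    summarize_gene,
    SampleMeta,
)

gene = GeneModel(
    gene_name="DEMO1", chrom="chr7", strand="+",
    tx_start=10_000, tx_end=40_000, cds_start=12_000, cds_end=38_000,
    exon_starts=(10_000, 20_000, 37_500), exon_ends=(12_500, 21_000, 40_000),
)

calls = [
    MicroDNACall("chr7", 8_500, 8_800, call_id="promoter_hit"),   # 2 kb upstream window
    MicroDNACall("chr7", 12_100, 12_300, call_id="exonic_hit"),
    MicroDNACall("chr7", 15_000, 15_400, call_id="intronic_hit"),
    MicroDNACall("chr7", 38_200, 38_400, call_id="utr3_hit"),
    MicroDNACall("chr7", 99_000, 99_300, call_id="intergenic_hit"),
]

peaks = PeakIndex({"LCL": [("chr7", 8_000, 10_000)]})
annotations = annotate_calls(calls, [gene], peaks)
for a in annotations:
    print(f"{a.call_id:15s} -> gene {a.gene_name or '-':6s} category {a.category:14s}"
          f" open-chromatin {dict(a.open_chromatin_flags)}")

meta = SampleMeta("P1_dx_plasma", "P1", "plasma", "diagnosis", 3_500_000)
summary = summarize_gene(
    [(a, meta.sample_id) for a in annotations if a.gene_name], {meta.sample_id: meta}
)[0]
print(f"\nper-gene summary for {summary.gene_name}: {summary.n_microdna} fragments,"
      f" category % {summary.category_pct}, LCL-peak % {summary.open_chromatin_pct}")
print("-> counts partition the fragment total; the promoter call also lies in "
      "an open-chromatin peak, as expected for transcriptionally active loci.")
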