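"""Simulate a synthetic three-stage cohort and describe it.

The generator plants an 11-gene disease/relapse signature (present with
probability 0.9 at diagnosis and relapse, never in remission) on top of a
0.05 per-sample background over the gene universe, draws bimodal fragment
lengths (modes ~150/294 bp, mean ~588 bp), and thins detection by sequencing
depth (relapse plasma is low-abundance and needs deep sequencing).
"""

import numpy as np

from microdna import CohortSimConfig, length_stats, simulate_cohort

cfg = CohortSimConfig(gene_universe=2000, seed=17)
cohort = simulate_cohort(cfg)

lengths = np.concatenate([(s.end - s.start) for s in cohort.samples])
mean, modes = length_stats(lengths, histogram_bin_bp=10)
print(f"samples: {len(cohort.samples)} "
      f"({len({s.meta.patient_id for s in cohort.samples})} patients, 2 tissues)")
print(f"fragment lengths: mean {mean:.0f} bp, top modes {modes[:2]} bp")

bm = [s for s in cohort.samples if s.meta.tissue == "BM"]
genes_per_sample = np.mean([len(s.detected_genes()) for s in bm])
print(f"microDNA-producing genes per BM sample: {genes_per_sample:.0f} "
      f"of {cfg.gene_universe} (background 0.05 + planted signature)")

for s in cohort.samples[:1]:
    fpm = 1e6 * s.detected.sum() / s.meta.mapped_reads
    print(f"example sample {s.meta.sample_id}: {int(s.detected.sum())} fragments, "
          f"{fpm:.1f} per million mapped reads")

shallow = [s for s in cohort.samples
           if s.meta.stage == "relapse" and s.meta.tissue == "plasma"]
print(f"relapse plasma detected fraction (deep resequencing on): "
      f"{np.mean([s.detected.mean() for s in shallow]):.3f}")
print("-> the emulated cohort reproduces the bimodal length profile and the "
      "~5% per-sample gene-production rate the analysis assumes.")
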