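"""End-to-end orchestration: emitted/real input files -> calls -> annotation
-> per-sample profiles -> per-tissue presence matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .annotation import GeneIndex, PeakIndex, annotate_calls
from .calling import CallerConfig, CallStats, call_sample
from .io import (
    GeneModel,
    SampleMeta,
    read_bed_intervals,
    read_chimeric_junctions,
    read_gene_models,
    read_sample_sheet,
)
from .metrics import SampleProfile
from .sharing import PresenceMatrix, build_presence_matrix

logger = logging.getLogger("microdna.pipeline")


@dataclass
class CohortResult:
    profiles: list[SampleProfile]
    stats: dict[str, CallStats]
    matrices: dict[str, PresenceMatrix]  # per tissue, empty genes dropped

    def matrix(self, tissue: str) -> PresenceMatrix:
        return self.matrices[tissue]


def profile_sample(
    junction_path: str | Path,
    meta: SampleMeta,
    gene_index: GeneIndex,
    caller_config: CallerConfig = CallerConfig(),
    peak_index: PeakIndex | None = None,
    strict: bool = False,
) -> tuple[SampleProfile, CallStats]:
    """Call, annotate and profile one sample from its junction file."""
    parsed = read_chimeric_junctions(junction_path, strict=strict)
    calls, stats = call_sample(parsed.records, caller_config, sample_id=meta.sample_id)
    annotations = annotate_calls(calls, gene_index, peak_index)
    profile = SampleProfile(
        sample_meta=meta,
        calls=calls,
        gene_of_call={a.call_id: a.gene_name for a in annotations},
    )
    return profile, stats


def run_cohort(
    cohort_dir: str | Path,
    caller_config: CallerConfig = CallerConfig(),
    genes: Sequence[GeneModel] | None = None,
    peak_paths: dict[str, str | Path] | None = None,
) -> CohortResult:
    """Run the pipeline over a cohort directory as laid out by the simulator:
    ``junctions/<sample_id>.junctions.tsv``, ``genes.refflat.tsv`` and
    ``sample_sheet.tsv`` (gene models may be supplied directly instead)."""
    cohort_dir = Path(cohort_dir)
    samples = read_sample_sheet(cohort_dir / "sample_sheet.tsv")
    if genes is None:
        genes = read_gene_models(cohort_dir / "genes.refflat.tsv", dialect="refflat")
    gene_index = GeneIndex(list(genes))
    peak_index = (
        PeakIndex({name: read_bed_intervals(p) for name, p in peak_paths.items()})
        if peak_paths
        else None
    )
    profiles: list[SampleProfile] = []
    stats: dict[str, CallStats] = {}
    for meta in samples:
        jpath = cohort_dir / "junctions" / f"{meta.sample_id}.junctions.tsv"
        profile, st = profile_sample(jpath, meta, gene_index, caller_config, peak_index)
        profiles.append(profile)
        stats[meta.sample_id] = st
    matrices = {}
    for tissue in sorted({m.sample_meta.tissue for m in profiles}):
        tissue_profiles = [p for p in profiles if p.sample_meta.tissue == tissue]
        matrices[tissue] = build_presence_matrix(tissue_profiles).drop_empty_genes()
    return CohortResult(profiles=profiles, stats=stats, matrices=matrices)
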