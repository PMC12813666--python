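"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a three-stage (diagnosis / relapse / remission),
two-tissue (BM / plasma) pediatric-leukemia cohort profiled for microDNA:

* every gene of a toy universe is produced independently per sample with a
  background probability (default 0.05 — the observed ~2,000 producing genes
  of a ~40,000-gene universe);
* a small set of planted *signature* genes is produced with high probability
  in disease-stage samples and never in remission;
* active genes emit geometric numbers of fragments whose lengths follow a
  bimodal mixture (modes ~150 and ~294 bp) plus a heavy right tail whose
  weight is solved at configuration time so the overall mean is ~588 bp;
* fragment detection is thinned by an exponential-saturation depth model,
  1 - exp(-lambda * depth * abundance); relapse plasma carries a low
  abundance factor, so it yields little at standard depth and recovers when
  resequenced deep (the two-pass design).

``emit_cohort_files`` writes per-sample chimeric-junction TSVs (with
read-level endpoint jitter), toy refFlat gene models, promoter peak BEDs, a
sample sheet and a truth-manifest JSON, so the full pipeline is testable
end-to-end against ground truth without any external downloads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import GeneModel, SampleMeta, write_sample_sheet
from .sharing import PresenceMatrix

DEFAULT_GROUPS = (("diagnosis", 25), ("relapse", 9), ("remission", 18))


@dataclass(frozen=True)
class CohortSimConfig:
    # cohort structure
    gene_universe: int = 2000  # 40_000 at full scale
    background_p: float = 0.05
    n_patients: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    tissues: tuple[str, ...] = ("BM", "plasma")
    n_signature_genes: int = 11
    present_prob_disease: float = 0.9
    present_prob_remission: float = 0.0
    n_later_relapse: int = 11  # diagnosis patients labeled as future relapse
    # fragment counts and junction-read support
    fragment_mean: float = 4.0  # geometric on {1, 2, ...}
    support_mean: float = 3.0
    support_min: int = 2
    # length mixture
    length_modes: tuple[float, float] = (150.0, 294.0)
    length_sigma: float = 0.1  # sharp nucleosomal-width peaks
    length_mean_target: float = 588.0
    tail_min: float = 294.0  # tail rises smoothly from the second mode upward
    tail_scale: float = 500.0  # gamma(shape 2) tail: zero density at onset
    min_length: int = 50
    max_length: int = 2000
    # toy genome layout
    gene_span: int = 6000
    gene_spacing: int = 10_000
    genes_per_chrom: int = 500
    promoter_bp: int = 2000
    promoter_bias: float = 0.2  # fraction of fragments placed in the promoter window
    peak_fractions: tuple[tuple[str, float], ...] = (("LCL", 0.6), ("BALL", 0.3))
    # depth model
    depth_lambda: float = 2e-6  # per mapped read
    standard_depth: int = 3_500_000
    deep_depth: int = 115_000_000
    relapse_plasma_abundance: float = 0.05
    relapse_plasma_deep: bool = True  # resequence relapse plasma at high depth
    ideal_detection: bool = False  # detection probability 1 everywhere
    # file emission
    jitter_bp: int = 2  # per-read endpoint jitter, <= caller cluster tolerance
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.background_p, self.present_prob_disease,
                     self.present_prob_remission, self.promoter_bias):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_signature_genes > self.gene_universe:
            raise ValueError("more signature genes than the gene universe")
        if self.fragment_mean < 1 or self.support_mean < self.support_min:
            raise ValueError("fragment/support means inconsistent")
        if self.jitter_bp < 0 or self.min_length >= self.max_length:
            raise ValueError("bad length/jitter configuration")
        if self.gene_span + self.promoter_bp > self.gene_spacing + self.gene_span:
            raise ValueError("gene spacing too small for the promoter window")

    # -- length mixture calibration ------------------------------------------
    def _tail_span(self) -> float:
        # tail truncated so jitter cannot push a call past the caller's window
        return (self.max_length - self.jitter_bp) - self.tail_min

    def _component_means(self) -> tuple[float, float, float]:
        s2 = self.length_sigma**2
        m1 = self.length_modes[0] * math.exp(1.5 * s2)  # lognormal, mode-parametrised
        m2 = self.length_modes[1] * math.exp(1.5 * s2)
        # mean of a gamma(shape 2, tail_scale) truncated to [0, span], + tail_min
        t = self._tail_span() / self.tail_scale
        q = math.exp(-t)
        num = 2.0 * (1 - q * (1 + t + t * t / 2))
        den = 1 - q * (1 + t)
        m_tail = self.tail_min + self.tail_scale * num / den
        return m1, m2, m_tail

    def tail_weight(self) -> float:
        """Tail weight solved so the mixture mean hits ``length_mean_target``."""
        m1, m2, m_tail = self._component_means()
        m12 = 0.5 * (m1 + m2)
        w = (self.length_mean_target - m12) / (m_tail - m12)
        if not 0 <= w < 1:
            raise ValueError("length mixture cannot reach the target mean")
        return w


def simulate_lengths(config: CohortSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` fragment lengths (bp, int) from the calibrated mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    wt = config.tail_weight()
    comp = rng.choice(3, size=n, p=[(1 - wt) / 2, (1 - wt) / 2, wt])
    sigma = config.length_sigma
    out = np.empty(n)
    for i, mode in enumerate(config.length_modes):
        mask = comp == i
        mu = math.log(mode) + sigma**2
        out[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    mask = comp == 2
    span = config._tail_span()
    n_tail = int(mask.sum())
    # gamma(shape 2) tail truncated by rejection: zero density at the onset
    # (no distortion of the second mode) and no pileup at the upper bound
    tail = rng.gamma(2.0, config.tail_scale, size=n_tail)
    while True:
        bad = tail > span
        if not bad.any():
            break
        tail[bad] = rng.gamma(2.0, config.tail_scale, size=int(bad.sum()))
    out[mask] = config.tail_min + tail
    # keep a jitter margin inside the caller's length window so that read-level
    # endpoint jitter can never push a clustered call outside [min, max]
    lo = config.min_length + config.jitter_bp
    hi = config.max_length - config.jitter_bp
    return np.clip(np.rint(out), lo, hi).astype(int)


# -- toy genome ---------------------------------------------------------------

def build_gene_models(config: CohortSimConfig) -> list[GeneModel]:
    """Lay the gene universe on a toy genome: fixed-size genes on alternating
    strands, three exons each, spaced so promoter windows never collide."""
    genes = []
    span = config.gene_span
    # relative exon layout: three exons with CDS trimmed inside the outer two
    e = [(0, span // 5), (2 * span // 5, 3 * span // 5), (4 * span // 5, span)]
    cds_lo, cds_hi = span // 10, span - span // 10
    for idx in range(config.gene_universe):
        chrom = f"chr{idx // config.genes_per_chrom + 1}"
        slot = idx % config.genes_per_chrom
        start = 5000 + slot * (config.gene_spacing + span)
        strand = "+" if idx % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_name=f"G{idx:05d}",
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=start + span,
                cds_start=start + cds_lo,
                cds_end=start + cds_hi,
                exon_starts=tuple(start + a for a, _ in e),
                exon_ends=tuple(start + b for _, b in e),
            )
        )
    return genes


def build_sample_sheet(config: CohortSimConfig) -> list[SampleMeta]:
    """Patients and samples: diagnosis patients P01..Pn, the relapse group a
    subset of them, remission drawn from the tail of the patient list; every
    patient/stage has one sample per tissue."""
    sizes = dict(config.n_patients)
    n_dx = sizes.get("diagnosis", 0)
    n_rel = sizes.get("relapse", 0)
    n_rem = sizes.get("remission", 0)
    n_total = max(n_dx, n_rel, n_rem)
    patients = [f"P{i + 1:02d}" for i in range(n_total)]
    stage_patients = {
        "diagnosis": patients[:n_dx],
        "relapse": patients[:n_rel],
        "remission": patients[max(0, n_total - n_rem):],
    }
    stage_tag = {"diagnosis": "dx", "relapse": "rel", "remission": "rem"}
    samples = []
    for stage, _ in config.n_patients:
        for pid in stage_patients[stage]:
            for tissue in config.tissues:
                deep = (
                    stage == "relapse" and tissue == "plasma" and config.relapse_plasma_deep
                )
                samples.append(
                    SampleMeta(
                        sample_id=f"{pid}_{stage_tag[stage]}_{tissue}",
                        patient_id=pid,
                        tissue=tissue,
                        stage=stage,
                        mapped_reads=config.deep_depth if deep else config.standard_depth,
                        later_relapse=(
                            ("yes" if int(pid[1:]) <= config.n_later_relapse else "no")
                            if stage == "diagnosis"
                            else "unknown"
                        ),
                        deep=deep,
                    )
                )
    return samples


# -- cohort simulation --------------------------------------------------------

@dataclass
class SimulatedSample:
    """One sample's true fragments (parallel arrays over fragments)."""

    meta: SampleMeta
    gene_idx: np.ndarray  # int, index into the gene universe
    start: np.ndarray  # 0-based half-open
    end: np.ndarray
    support: np.ndarray  # junction reads per fragment
    detected: np.ndarray  # bool, survives depth thinning

    @property
    def n_fragments(self) -> int:
        return len(self.gene_idx)

    def active_genes(self) -> np.ndarray:
        return np.unique(self.gene_idx)

    def detected_genes(self) -> np.ndarray:
        return np.unique(self.gene_idx[self.detected])


@dataclass
class SyntheticCohort:
    config: CohortSimConfig
    genes: list[GeneModel]
    signature_genes: list[str]
    samples: list[SimulatedSample]

    def gene_names(self) -> list[str]:
        return [g.gene_name for g in self.genes]

    def _presence(self, tissue: str | None, which: str) -> PresenceMatrix:
        names = np.asarray(self.gene_names(), dtype=object)
        keep = [s for s in self.samples if tissue is None or s.meta.tissue == tissue]
        detected = np.zeros((len(names), len(keep)), dtype=bool)
        for j, s in enumerate(keep):
            idx = s.active_genes() if which == "truth" else s.detected_genes()
            detected[idx, j] = True
        return PresenceMatrix(
            genes=list(names), samples=[s.meta for s in keep], detected=detected
        )

    def truth_presence(self, tissue: str | None = None) -> PresenceMatrix:
        """Activation ground truth: gene x sample, independent of detection."""
        return self._presence(tissue, "truth")

    def observed_presence(self, tissue: str | None = None) -> PresenceMatrix:
        """Presence after depth thinning (what a perfect caller would see)."""
        return self._presence(tissue, "observed")


def _detection_probability(config: CohortSimConfig, meta: SampleMeta) -> float:
    if config.ideal_detection:
        return 1.0
    abundance = (
        config.relapse_plasma_abundance
        if (meta.stage == "relapse" and meta.tissue == "plasma")
        else 1.0
    )
    return 1.0 - math.exp(-config.depth_lambda * meta.mapped_reads * abundance)


def _place_fragments(
    config: CohortSimConfig,
    gene: GeneModel,
    lengths: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement within the gene span, or within the promoter window
    with probability ``promoter_bias`` when the fragment fits there."""
    starts = np.empty(len(lengths), dtype=int)
    p_lo, p_hi = gene.promoter_window(config.promoter_bp)
    for i, length in enumerate(lengths):
        length = int(min(length, gene.tx_end - gene.tx_start))
        in_promoter = rng.random() < config.promoter_bias and p_hi - p_lo >= length
        lo, hi = (p_lo, p_hi) if in_promoter else (gene.tx_start, gene.tx_end)
        starts[i] = rng.integers(lo, hi - length + 1)
        lengths[i] = length
    return starts, starts + lengths


def simulate_cohort(config: CohortSimConfig = CohortSimConfig()) -> SyntheticCohort:
    """Simulate a full cohort: activity, fragments, lengths, depth thinning.

    Deterministic under ``config.seed``; a fixed config and seed reproduce
    the cohort (and any files later emitted from it) exactly.
    """
    rng = np.random.default_rng(config.seed)
    genes = build_gene_models(config)
    g = config.gene_universe
    sig_idx = np.sort(rng.choice(g, size=config.n_signature_genes, replace=False))
    is_sig = np.zeros(g, dtype=bool)
    is_sig[sig_idx] = True
    samples = []
    for meta in build_sample_sheet(config):
        active = rng.random(g) < config.background_p
        disease = meta.stage in ("diagnosis", "relapse")
        sig_p = config.present_prob_disease if disease else config.present_prob_remission
        active[sig_idx] = rng.random(len(sig_idx)) < sig_p
        active_idx = np.flatnonzero(active)
        n_frags = rng.geometric(1.0 / config.fragment_mean, size=len(active_idx))
        gene_idx = np.repeat(active_idx, n_frags)
        total = int(n_frags.sum())
        lengths = (
            simulate_lengths(config, total, rng) if total else np.empty(0, dtype=int)
        )
        starts = np.empty(total, dtype=int)
        ends = np.empty(total, dtype=int)
        pos = 0
        for ai, nf in zip(active_idx, n_frags):
            s, e = _place_fragments(config, genes[ai], lengths[pos : pos + nf], rng)
            starts[pos : pos + nf] = s
            ends[pos : pos + nf] = e
            pos += nf
        support = config.support_min + rng.poisson(
            config.support_mean - config.support_min, size=total
        )
        p_det = _detection_probability(config, meta)
        detected = (
            np.ones(total, dtype=bool) if p_det >= 1.0 else rng.random(total) < p_det
        )
        samples.append(
            SimulatedSample(
                meta=meta,
                gene_idx=gene_idx,
                start=starts,
                end=ends,
                support=support.astype(int),
                detected=detected,
            )
        )
    return SyntheticCohort(
        config=config,
        genes=genes,
        signature_genes=[genes[i].gene_name for i in sig_idx],
        samples=samples,
    )


# -- file emission ------------------------------------------------------------

def write_refflat(genes: Sequence[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gm in genes:
            fh.write(
                "\t".join(
                    [
                        gm.gene_name,
                        gm.gene_name + ".1",
                        gm.chrom,
                        gm.strand,
                        str(gm.tx_start),
                        str(gm.tx_end),
                        str(gm.cds_start),
                        str(gm.cds_end),
                        str(len(gm.exon_starts)),
                        ",".join(map(str, gm.exon_starts)) + ",",
                        ",".join(map(str, gm.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )


def emit_cohort_files(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk: per-sample junction TSVs (detected fragments
    only, ``support`` reads each with endpoint jitter), refFlat gene models,
    promoter-peak BEDs, sample sheet and a truth-manifest JSON.

    Byte-deterministic for a fixed config+seed (emission randomness derives
    from the cohort seed).
    """
    out = Path(out_dir)
    (out / "junctions").mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xEC0DA]))

    paths: dict[str, Path] = {}
    for sample in cohort.samples:
        path = out / "junctions" / f"{sample.meta.sample_id}.junctions.tsv"
        with path.open("w") as fh:
            fh.write("# chrom_donor\tpos_donor\tstrand_donor\tchrom_acceptor\t"
                     "pos_acceptor\tstrand_acceptor\tjunction_type\trepeat_len\tread_id\n")
            for fi in np.flatnonzero(sample.detected):
                gm = cohort.genes[sample.gene_idx[fi]]
                start, end = int(sample.start[fi]), int(sample.end[fi])
                for r in range(int(sample.support[fi])):
                    j1 = int(rng.integers(0, cfg.jitter_bp + 1))
                    j2 = int(rng.integers(0, cfg.jitter_bp + 1))
                    acc = start + 1 + j1  # 1-based acceptor (circle start)
                    don = end + j2  # 1-based donor (circle end)
                    fh.write(
                        f"{gm.chrom}\t{don}\t{gm.strand}\t{gm.chrom}\t{acc}\t"
                        f"{gm.strand}\t0\t0\t{sample.meta.sample_id}_f{fi}_r{r}\n"
                    )
        paths[sample.meta.sample_id] = path

    genes_path = out / "genes.refflat.tsv"
    write_refflat(cohort.genes, genes_path)
    paths["genes"] = genes_path

    for name, fraction in cfg.peak_fractions:
        chosen = rng.random(len(cohort.genes)) < fraction
        peak_path = out / f"peaks_{name}.bed"
        with peak_path.open("w") as fh:
            for gm, keep in zip(cohort.genes, chosen):
                if keep:
                    lo, hi = gm.promoter_window(cfg.promoter_bp)
                    fh.write(f"{gm.chrom}\t{lo}\t{hi}\n")
        paths[f"peaks_{name}"] = peak_path

    sheet_path = out / "sample_sheet.tsv"
    write_sample_sheet([s.meta for s in cohort.samples], sheet_path)
    paths["sample_sheet"] = sheet_path

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "signature_genes": cohort.signature_genes,
        "samples": {
            s.meta.sample_id: {
                "n_fragments_true": int(s.n_fragments),
                "n_fragments_detected": int(s.detected.sum()),
                "true_genes": [cohort.genes[i].gene_name for i in s.active_genes()],
                "detected_genes": [cohort.genes[i].gene_name for i in s.detected_genes()],
            }
            for s in cohort.samples
        },
    }
    manifest_path = out / "truth_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["truth_manifest"] = manifest_path
    return paths
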