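"""Gene-level presence matrix, cross-stage sharing, and the binomial null.

The unit of analysis is the *microDNA-producing gene*: a gene from which at
least one circle was called in a sample.  Sharing within a stage counts
distinct patients (not samples).  The expected amount of sharing under
chance alone follows a binomial null: each gene is produced independently in
each individual with probability ``p`` (default 0.05, i.e. ~2,000 producing
genes of a ~40,000-gene universe), so the probability a gene is "shared"
within a stage of ``n`` individuals is P(Binomial(n, p) >= k) with k = 2.
Stage-level shared sets combine across stages under independence, giving
closed-form expected frequencies for the seven Venn regions of the
diagnosis/relapse/remission set trio, which the observed partition is tested
against with a Pearson chi-square.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleMeta
from .metrics import SampleProfile

logger = logging.getLogger("microdna.sharing")

STAGE_ORDER = ("diagnosis", "relapse", "remission")
REGIONS = (
    ("diagnosis",),
    ("relapse",),
    ("remission",),
    ("diagnosis", "relapse"),
    ("diagnosis", "remission"),
    ("relapse", "remission"),
    ("diagnosis", "relapse", "remission"),
)


@dataclass
class PresenceMatrix:
    """Binary gene x sample detection indicator with sample metadata."""

    genes: list[str]
    samples: list[SampleMeta]
    detected: np.ndarray  # bool, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != (len(self.genes), len(self.samples)):
            raise ValueError("detected matrix shape inconsistent with labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.detected,
            index=pd.Index(self.genes, name="gene"),
            columns=[s.sample_id for s in self.samples],
        )

    def sample_columns(self, stage: str | None = None, tissue: str | None = None,
                       sample_ids: set[str] | None = None) -> list[int]:
        cols = []
        for j, s in enumerate(self.samples):
            if stage is not None and s.stage != stage:
                continue
            if tissue is not None and s.tissue != tissue:
                continue
            if sample_ids is not None and s.sample_id not in sample_ids:
                continue
            cols.append(j)
        return cols

    def patient_counts(self, stage: str | None = None, tissue: str | None = None,
                       sample_ids: set[str] | None = None) -> pd.Series:
        """Per gene: number of distinct patients with >= 1 detection in the stratum."""
        cols = self.sample_columns(stage, tissue, sample_ids)
        patients = {}
        for j in cols:
            patients.setdefault(self.samples[j].patient_id, []).append(j)
        counts = np.zeros(len(self.genes), dtype=int)
        for pid, js in patients.items():
            counts += self.detected[:, js].any(axis=1)
        return pd.Series(counts, index=self.genes)

    def gene_sets_by_sample(self) -> dict[str, set[str]]:
        genes = np.asarray(self.genes, dtype=object)
        return {
            s.sample_id: set(genes[self.detected[:, j]])
            for j, s in enumerate(self.samples)
        }

    def drop_empty_genes(self) -> "PresenceMatrix":
        keep = self.detected.any(axis=1)
        return PresenceMatrix(
            genes=[g for g, k in zip(self.genes, keep) if k],
            samples=list(self.samples),
            detected=self.detected[keep],
        )


def build_presence_matrix(
    profiles: Sequence[SampleProfile], gene_universe: Sequence[str] | None = None
) -> PresenceMatrix:
    """Build detection(g, s) = 1 iff sample ``s`` has >= 1 call assigned to gene ``g``.

    Intergenic calls are excluded.  With ``gene_universe`` given, rows cover
    the full universe (all-zero rows permitted, e.g. simulator truth);
    otherwise only genes observed somewhere appear.
    """
    per_sample = [p.genes for p in profiles]
    if gene_universe is None:
        genes = sorted(set().union(*per_sample)) if per_sample else []
    else:
        genes = list(gene_universe)
    gidx = {g: i for i, g in enumerate(genes)}
    detected = np.zeros((len(genes), len(profiles)), dtype=bool)
    for j, gene_set in enumerate(per_sample):
        for g in gene_set:
            if g in gidx:
                detected[gidx[g], j] = True
    return PresenceMatrix(
        genes=genes, samples=[p.sample_meta for p in profiles], detected=detected
    )


def stage_shared_set(
    matrix: PresenceMatrix, stage: str, tissue: str | None = None, k: int = 2
) -> set[str]:
    """Genes detected in >= k distinct patients of the given stage (and tissue)."""
    cols = matrix.sample_columns(stage, tissue)
    n_patients = len({matrix.samples[j].patient_id for j in cols})
    if n_patients < k:
        logger.warning(
            "stage %s/%s has %d patients < k=%d; shared set is empty",
            stage, tissue, n_patients, k,
        )
        return set()
    counts = matrix.patient_counts(stage, tissue)
    return set(counts.index[counts >= k])


def venn_partition(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Exact 7-region partition counts of three sets (A, B, C)."""
    return {
        "A": len(set_a - set_b - set_c),
        "B": len(set_b - set_a - set_c),
        "C": len(set_c - set_a - set_b),
        "AB": len((set_a & set_b) - set_c),
        "AC": len((set_a & set_c) - set_b),
        "BC": len((set_b & set_c) - set_a),
        "ABC": len(set_a & set_b & set_c),
    }


@dataclass(frozen=True)
class BinomialNullSpec:
    """Parameters of the expected-sharing binomial null."""

    p: float = 0.05
    group_sizes: tuple[tuple[str, int], ...] = (
        ("diagnosis", 25),
        ("relapse", 9),
        ("remission", 18),
    )
    k: int = 2
    gene_universe: int = 40_000

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if any(n < 1 for _, n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if self.k < 1 or self.gene_universe < 1:
            raise ValueError("k and gene universe must be >= 1")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.group_sizes)


def binomial_sharing_probability(n: int, p: float, k: int = 2) -> float:
    """P(X >= k) for X ~ Binomial(n, p): the chance a gene is produced in at
    least k of n individuals under the null."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if k <= 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p))


@dataclass
class SharingSummary:
    """Stage-level shared sets and their Venn partition (patient-distinct)."""

    shared_sets: dict[str, set[str]]
    region_counts: dict[tuple[str, ...], int]
    nonshared_counts: dict[str, int]
    pairwise_shared: dict[tuple[str, str], int]


def summarize_sharing(
    matrix: PresenceMatrix, tissue: str | None = None, k: int = 2
) -> SharingSummary:
    """Shared set per stage, 7-region Venn partition, non-shared and pairwise counts."""
    stages = [s for s in STAGE_ORDER if matrix.sample_columns(s, tissue)]
    shared = {s: stage_shared_set(matrix, s, tissue, k) for s in stages}
    sets = {s: shared.get(s, set()) for s in STAGE_ORDER}
    venn = venn_partition(sets["diagnosis"], sets["relapse"], sets["remission"])
    label = {"diagnosis": "A", "relapse": "B", "remission": "C"}
    region_counts = {
        region: venn["".join(label[s] for s in region)] for region in REGIONS
    }
    nonshared = {}
    for s in stages:
        counts = matrix.patient_counts(s, tissue)
        nonshared[s] = int(((counts >= 1) & (counts < k)).sum())
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(STAGE_ORDER, 2)
    }
    return SharingSummary(shared, region_counts, nonshared, pairwise)


def region_probabilities(spec: BinomialNullSpec) -> dict[tuple[str, ...], float]:
    """Probability of each of the 8 sharing outcomes (7 regions + none) for one
    gene under stage-independent binomial sharing."""
    q = {
        stage: binomial_sharing_probability(n, spec.p, spec.k)
        for stage, n in spec.group_sizes
    }
    out: dict[tuple[str, ...], float] = {}
    stages = [s for s, _ in spec.group_sizes]
    for r in range(len(stages) + 1):
        for combo in itertools.combinations(stages, r):
            prob = 1.0
            for s in stages:
                prob *= q[s] if s in combo else 1.0 - q[s]
            out[combo] = prob
    return out


def expected_region_frequencies(
    spec: BinomialNullSpec, mode: str = "conditional"
) -> dict[tuple[str, ...], float]:
    """Expected 7-region frequencies/counts under the binomial null.

    ``conditional``: probabilities renormalised over the 7 non-empty regions
    (frequencies relative to the total number of shared genes).
    ``absolute``: expected gene counts, gene_universe x region probability.
    """
    probs = region_probabilities(spec)
    regions = {r: p for r, p in probs.items() if r}
    if mode == "absolute":
        return {r: spec.gene_universe * p for r, p in regions.items()}
    if mode == "conditional":
        total = sum(regions.values())
        return {r: p / total for r, p in regions.items()}
    raise ValueError(f"unknown mode {mode!r}")


def observed_vs_expected_chisq(
    observed: Mapping[tuple[str, ...], float] | Sequence[float],
    expected: Mapping[tuple[str, ...], float] | Sequence[float],
) -> tuple[float, int, float]:
    """Pearson chi-square of observed region counts against expected ones.

    Expected counts are rescaled to the observed total; regions whose
    rescaled expectation falls below 1 are merged into the smallest remaining
    region (logged).  Returns (statistic, df, p).
    """
    if isinstance(observed, Mapping):
        keys = list(observed)
        obs = np.asarray([observed[k] for k in keys], dtype=float)
        exp = np.asarray([expected[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(list(observed), dtype=float)
        exp = np.asarray(list(expected), dtype=float)
        if obs.shape != exp.shape:
            raise ValueError("observed and expected must align")
    if obs.sum() <= 0:
        raise ValueError("all-zero observed counts")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    exp = exp * (obs.sum() / exp.sum())
    while len(exp) > 1 and exp.min() < 1.0:
        i = int(np.argmin(exp))
        rest = [j for j in range(len(exp)) if j != i]
        j = rest[int(np.argmin(exp[rest]))]
        logger.info("merging region with expected %.3f into its smallest neighbour", exp[i])
        exp[j] += exp[i]
        obs[j] += obs[i]
        exp = np.delete(exp, i)
        obs = np.delete(obs, i)
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return stat, df, float(sps.chi2.sf(stat, df))
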