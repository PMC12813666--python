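"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Chimeric-junction files carry 1-based positions (aligner convention); every
internal coordinate in this package is 0-based half-open; every emitted BED
is 0-based half-open.  The junction dialect is a >=9-column TSV mirroring the
first columns of STAR's ``Chimeric.out.junction``: donor chrom/pos/strand,
acceptor chrom/pos/strand, junction type, one ignored repeat-length column,
read name.  Extra columns are ignored; ``#`` header lines are permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("microdna.io")

TISSUES = ("BM", "plasma")
STAGES = ("diagnosis", "relapse", "remission")
RELAPSE_LABELS = ("yes", "no", "unknown")


class ParseError(ValueError):
    """Raised for unrecoverable format problems (or any problem in strict mode)."""


@dataclass(frozen=True)
class JunctionRecord:
    """One chimeric junction emitted by the aligner (1-based positions)."""

    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_type: int
    read_id: str

    def __post_init__(self) -> None:
        if self.pos_donor < 1 or self.pos_acceptor < 1:
            raise ValueError("junction positions are 1-based and must be >= 1")
        if self.strand_donor not in "+-" or self.strand_acceptor not in "+-":
            raise ValueError(f"bad strand in junction {self.read_id!r}")
        if not self.chrom_donor or not self.chrom_acceptor:
            raise ValueError("chromosome names must be non-empty")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample (one patient/tissue/stage)."""

    sample_id: str
    patient_id: str
    tissue: str  # BM | plasma
    stage: str  # diagnosis | relapse | remission
    mapped_reads: int
    later_relapse: str = "unknown"  # yes | no | unknown
    deep: bool = False  # resequenced at high depth (relapse plasma two-pass)

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for {self.sample_id}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r} for {self.sample_id}")
        if self.later_relapse not in RELAPSE_LABELS:
            raise ValueError(f"bad later_relapse {self.later_relapse!r}")
        if self.mapped_reads <= 0:
            raise ValueError(f"mapped_reads must be positive ({self.sample_id})")


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript model, 0-based half-open, exons sorted and disjoint."""

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand for gene {self.gene_name}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"tx_start >= tx_end for gene {self.gene_name}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"inconsistent exon lists for gene {self.gene_name}")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"exon outside tx span for gene {self.gene_name}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons overlap/unsorted for gene {self.gene_name}")
            prev_end = e
        if self.cds_start != self.cds_end:  # coding
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"CDS outside tx span for gene {self.gene_name}")

    @property
    def coding(self) -> bool:
        return self.cds_start != self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter_window(self, promoter_bp: int = 2000) -> tuple[int, int]:
        """The ``promoter_bp`` region immediately upstream of the TSS."""
        if self.strand == "+":
            return max(0, self.tx_start - promoter_bp), self.tx_start
        return self.tx_end, self.tx_end + promoter_bp


@dataclass
class ParsedJunctions:
    """Junction records plus a count of malformed rows skipped in lenient mode."""

    records: list[JunctionRecord]
    n_malformed: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_chimeric_junctions(path: str | Path, strict: bool = False) -> ParsedJunctions:
    """Read a chimeric-junction TSV (dialect documented in the module docstring).

    Malformed rows are skipped and counted unless ``strict`` is set, in which
    case the first malformed row raises :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[JunctionRecord] = []
    n_bad = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 9:
                    raise ValueError(f"expected >=9 columns, got {len(fields)}")
                records.append(
                    JunctionRecord(
                        chrom_donor=fields[0],
                        pos_donor=int(fields[1]),
                        strand_donor=fields[2],
                        chrom_acceptor=fields[3],
                        pos_acceptor=int(fields[4]),
                        strand_acceptor=fields[5],
                        junction_type=int(fields[6]),
                        read_id=fields[8],
                    )
                )
            except ValueError as exc:
                if strict:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d malformed junction rows", path, n_bad)
    return ParsedJunctions(records, n_bad)


def _read_refflat_row(fields: Sequence[str], lineno: int) -> GeneModel:
    # refFlat: geneName txName chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds  (coordinates already 0-based half-open)
    n_exons = int(fields[8])
    starts = tuple(int(x) for x in fields[9].rstrip(",").split(",") if x)
    ends = tuple(int(x) for x in fields[10].rstrip(",").split(",") if x)
    if len(starts) != n_exons or len(ends) != n_exons:
        raise ParseError(f"row {lineno}: exon list inconsistent with exonCount")
    return GeneModel(
        gene_name=fields[0],
        chrom=fields[2],
        strand=fields[3],
        tx_start=int(fields[4]),
        tx_end=int(fields[5]),
        cds_start=int(fields[6]),
        cds_end=int(fields[7]),
        exon_starts=starts,
        exon_ends=ends,
    )


def _read_bed12_row(fields: Sequence[str], lineno: int) -> GeneModel:
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    thick_start, thick_end = int(fields[6]), int(fields[7])
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"row {lineno}: block list inconsistent with blockCount")
    exon_starts = tuple(start + o for o in offsets)
    exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
    return GeneModel(
        gene_name=name,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        cds_start=thick_start,
        cds_end=thick_end,
        exon_starts=exon_starts,
        exon_ends=exon_ends,
    )


def read_gene_models(path: str | Path, dialect: str = "refflat") -> list[GeneModel]:
    """Read gene models from a refFlat TSV or BED12 file.

    Output coordinates are 0-based half-open regardless of dialect.  An exon
    list inconsistent with its span is fatal, reported with the row number.
    """
    if dialect not in ("refflat", "bed12"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    genes: list[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "refflat":
                    genes.append(_read_refflat_row(fields, lineno))
                else:
                    genes.append(_read_bed12_row(fields, lineno))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


SAMPLE_SHEET_COLUMNS = ("sample_id", "patient_id", "tissue", "stage", "mapped_reads")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the cohort sample sheet (TSV with named columns).

    ``later_relapse`` and ``deep`` columns are optional (defaulting to
    ``unknown`` and ``False``); duplicate sample ids and unknown tissue/stage
    tokens are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated sample_id {sorted(set(dup))}")
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    patient_id=row["patient_id"],
                    tissue=row["tissue"],
                    stage=row["stage"],
                    mapped_reads=int(row["mapped_reads"]),
                    later_relapse=(
                        row["later_relapse"]
                        if "later_relapse" in df.columns and pd.notna(row.get("later_relapse"))
                        else "unknown"
                    ),
                    deep=(
                        str(row["deep"]).lower() in ("1", "true", "yes")
                        if "deep" in df.columns and pd.notna(row.get("deep"))
                        else False
                    ),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "patient_id": [s.patient_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "stage": [s.stage for s in samples],
            "mapped_reads": [s.mapped_reads for s in samples],
            "later_relapse": [s.later_relapse for s in samples],
            "deep": [int(s.deep) for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: Iterable, path: str | Path) -> None:
    """Write microDNA calls as BED6 (name = call id, score = junction support)."""
    with Path(path).open("w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.call_id}\t{c.support}\t{c.strand}\n")


def read_calls_bed(path: str | Path) -> list:
    """Read BED6 calls written by :func:`write_calls_bed` (round-trip inverse)."""
    from .calling import MicroDNACall  # local import to avoid a cycle

    calls = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            calls.append(
                MicroDNACall(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    support=int(score),
                    call_id=name,
                )
            )
    return calls


def write_bed3(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file as (chrom, start, end)."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write a presence matrix as TSV: genes as rows, sample ids as columns, {0,1} cells."""
    df = matrix.to_frame().astype(int)
    df.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path: str | Path, samples: Sequence[SampleMeta]):
    """Read a presence matrix written by :func:`write_matrix_tsv`.

    The TSV stores only detection states; ``samples`` re-attaches the sample
    metadata (matched by sample id, order taken from the file).
    """
    from .sharing import PresenceMatrix

    df = pd.read_csv(path, sep="\t", index_col="gene")
    by_id = {s.sample_id: s for s in samples}
    missing = [c for c in df.columns if c not in by_id]
    if missing:
        raise ParseError(f"{path}: no metadata for sample columns {missing}")
    meta = [by_id[c] for c in df.columns]
    return PresenceMatrix(
        genes=list(df.index), samples=meta, detected=df.to_numpy(dtype=bool)
    )
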