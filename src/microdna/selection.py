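"""Stepwise derivation of the disease/relapse-specific microDNA gene panel.

The panel is built first in bone marrow, then confirmed in plasma: a gene
must produce microDNA in >= 2 diagnosis BM patients, be absent from every
remission BM sample, persist in >= 2 relapse BM patients (the BM
relapse-specific set), then likewise be present in >= 2 diagnosis plasma
patients, absent from all remission plasma, and confirmed in >= 2 relapse
plasma patients.  Counting is by distinct patient at every step.  The
relapse-plasma confirmation may be restricted to a designated subset of
samples (e.g. those resequenced at high depth), mirroring a two-pass design
where low-yield relapse plasma is sequenced deeper before confirmation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .sharing import PresenceMatrix


@dataclass(frozen=True)
class SelectionThresholds:
    min_dx_bm: int = 2
    min_rel_bm: int = 2
    min_dx_plasma: int = 2
    min_rel_plasma: int = 2
    remission_max: int = 0  # absent in ALL remission samples, both tissues

    def __post_init__(self) -> None:
        if min(self.min_dx_bm, self.min_rel_bm, self.min_dx_plasma,
               self.min_rel_plasma, self.remission_max) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class SignaturePanel:
    """Final panel plus the ordered audit trail of the stepwise filters."""

    genes: list[str]
    trace: list[tuple[str, set[str]]]
    bm_relapse_specific: set[str]  # survivors of the BM-only steps (1-3)
    provenance: dict

    def __post_init__(self) -> None:
        sizes = [len(s) for _, s in self.trace]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("trace gene counts must be non-increasing")
        if self.trace and set(self.genes) != self.trace[-1][1]:
            raise ValueError("final genes must equal the last trace entry")


def _matrix_fingerprint(matrix: PresenceMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(matrix.genes).encode())
    h.update(",".join(s.sample_id for s in matrix.samples).encode())
    h.update(np.packbits(matrix.detected).tobytes())
    return h.hexdigest()[:16]


def _require_stratum(matrix: PresenceMatrix, stage: str, tissue: str) -> None:
    if not matrix.sample_columns(stage, tissue):
        raise ValueError(f"no samples for stratum {stage}/{tissue}")


def select_signature(
    bm: PresenceMatrix,
    plasma: PresenceMatrix,
    thresholds: SelectionThresholds = SelectionThresholds(),
    relapse_plasma_subset: set[str] | None = None,
) -> SignaturePanel:
    """Apply the six stepwise filters and return the panel with its trace.

    Filters, in order (counts are distinct patients): (1) >= min_dx_bm at
    diagnosis BM; (2) <= remission_max remission BM patients; (3) >=
    min_rel_bm at relapse BM; (4) >= min_dx_plasma at diagnosis plasma;
    (5) <= remission_max remission plasma patients; (6) >= min_rel_plasma at
    relapse plasma (optionally evaluated on ``relapse_plasma_subset`` sample
    ids only).  The final set is an intersection of monotone filters, hence
    independent of step order; the trace is not.
    """
    for stage in ("diagnosis", "relapse", "remission"):
        _require_stratum(bm, stage, "BM")
        _require_stratum(plasma, stage, "plasma")

    t = thresholds
    steps = [
        ("dx_bm_ge", bm, dict(stage="diagnosis", tissue="BM"), ">=", t.min_dx_bm),
        ("remission_bm_le", bm, dict(stage="remission", tissue="BM"), "<=", t.remission_max),
        ("rel_bm_ge", bm, dict(stage="relapse", tissue="BM"), ">=", t.min_rel_bm),
        ("dx_plasma_ge", plasma, dict(stage="diagnosis", tissue="plasma"), ">=", t.min_dx_plasma),
        ("remission_plasma_le", plasma, dict(stage="remission", tissue="plasma"), "<=", t.remission_max),
        (
            "rel_plasma_ge",
            plasma,
            dict(stage="relapse", tissue="plasma", sample_ids=relapse_plasma_subset),
            ">=",
            t.min_rel_plasma,
        ),
    ]

    survivors = set(bm.genes) | set(plasma.genes)
    trace: list[tuple[str, set[str]]] = []
    bm_relapse_specific: set[str] = set()
    for i, (name, matrix, stratum, op, threshold) in enumerate(steps, start=1):
        counts = matrix.patient_counts(**stratum)
        passing = set()
        for g in survivors:
            c = int(counts.get(g, 0))
            ok = c >= threshold if op == ">=" else c <= threshold
            if ok:
                passing.add(g)
        survivors = passing
        trace.append((f"{name}{threshold}", set(survivors)))
        if i == 3:
            bm_relapse_specific = set(survivors)

    return SignaturePanel(
        genes=sorted(survivors),
        trace=trace,
        bm_relapse_specific=bm_relapse_specific,
        provenance={
            "thresholds": t,
            "bm_fingerprint": _matrix_fingerprint(bm),
            "plasma_fingerprint": _matrix_fingerprint(plasma),
            "relapse_plasma_subset": sorted(relapse_plasma_subset)
            if relapse_plasma_subset is not None
            else None,
        },
    )
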