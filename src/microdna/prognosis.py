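"""Prognostic evaluation of a gene panel via gene x patient binary events.

Each panel gene contributes one binary detection event per patient in
diagnosis plasma; events are tallied into a 2x2 table by later-relapse
outcome.  Effect size is the odds ratio with a Woolf (log-scale normal)
95% CI, using the Haldane–Anscombe +0.5 correction when a cell is zero;
significance is a one-tailed Pearson chi-square (1 df, no continuity
correction), halved in the pre-stated direction.  A patient-level rule
(>= k panel genes detected) gives per-group positive fractions.

Gene x patient events are treated as independent, as in the source design;
within-patient correlation is a documented caveat, reported in the result
metadata rather than corrected for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats as sps

from .selection import SignaturePanel
from .sharing import PresenceMatrix

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EventTable2x2:
    """Gene x patient detection events: (a, b) relapse group detected/not,
    (c, d) non-relapse group detected/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def relapse_frequency(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def nonrelapse_frequency(self) -> float:
        return self.c / (self.c + self.d)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_one_tailed: float | None
    frequencies: dict[str, float]
    haldane_corrected: bool = False
    note: str = "gene x patient events treated as independent"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def build_event_table(
    panel: SignaturePanel | Sequence[str],
    dx_plasma_matrix: PresenceMatrix,
    labels: Mapping[str, str],
    allow_unknown: bool = False,
) -> EventTable2x2:
    """Tally one event per (panel gene, diagnosis-plasma patient) by outcome.

    ``labels`` maps patient_id -> 'relapse' | 'no-relapse'.  An unlabeled
    patient is fatal unless ``allow_unknown``, in which case it is excluded.
    """
    genes = list(panel.genes) if isinstance(panel, SignaturePanel) else list(panel)
    if not genes:
        raise ValueError("panel is empty")
    counts = {}  # patient -> number of panel genes detected
    cols = dx_plasma_matrix.sample_columns(stage="diagnosis", tissue="plasma")
    if not cols:
        raise ValueError("matrix has no diagnosis plasma samples")
    gidx = {g: i for i, g in enumerate(dx_plasma_matrix.genes)}
    for j in cols:
        pid = dx_plasma_matrix.samples[j].patient_id
        det = {g for g in genes if g in gidx and dx_plasma_matrix.detected[gidx[g], j]}
        counts[pid] = counts.get(pid, set()) | det
    a = b = c = d = 0
    for pid, detected in counts.items():
        if pid not in labels:
            if allow_unknown:
                continue
            raise ValueError(f"patient {pid} has no relapse label")
        k = len(detected)
        if labels[pid] == "relapse":
            a += k
            b += len(genes) - k
        elif labels[pid] == "no-relapse":
            c += k
            d += len(genes) - k
        else:
            raise ValueError(f"bad label {labels[pid]!r} for patient {pid}")
    return EventTable2x2(a, b, c, d)


def one_tailed_chisq(table: EventTable2x2, direction: str = "relapse-enriched") -> float | None:
    """One-tailed Pearson chi-square p (1 df, no continuity correction).

    p = p_two/2 when the observed effect lies in the stated direction, else
    1 - p_two/2.  A zero margin makes the statistic undefined (returns None).
    """
    if direction != "relapse-enriched":
        raise ValueError(f"unknown direction {direction!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return None
    stat = n * (a * d - b * c) ** 2 / margins
    p_two = float(sps.chi2.sf(stat, 1))
    in_direction = table.relapse_frequency >= table.nonrelapse_frequency
    return p_two / 2 if in_direction else 1 - p_two / 2


def odds_ratio_woolf(table: EventTable2x2) -> OddsRatioResult:
    """Odds ratio with Woolf 95% CI: exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
    cells) for the OR and CI, flagged in the result; reported detection
    frequencies always use the raw counts.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("empty outcome group")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=orr,
        ci_low=math.exp(math.log(orr) - Z95 * se),
        ci_high=math.exp(math.log(orr) + Z95 * se),
        p_one_tailed=one_tailed_chisq(table),
        frequencies={
            "relapse": table.relapse_frequency,
            "no-relapse": table.nonrelapse_frequency,
        },
        haldane_corrected=corrected,
    )


def patient_level_rule(
    panel: SignaturePanel | Sequence[str],
    dx_plasma_matrix: PresenceMatrix,
    labels: Mapping[str, str],
    k: int = 2,
    allow_unknown: bool = False,
) -> dict[str, float]:
    """Per-group fraction of patients with >= k panel genes detected at diagnosis."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = list(panel.genes) if isinstance(panel, SignaturePanel) else list(panel)
    cols = dx_plasma_matrix.sample_columns(stage="diagnosis", tissue="plasma")
    gidx = {g: i for i, g in enumerate(dx_plasma_matrix.genes)}
    per_patient: dict[str, set[str]] = {}
    for j in cols:
        pid = dx_plasma_matrix.samples[j].patient_id
        det = {g for g in genes if g in gidx and dx_plasma_matrix.detected[gidx[g], j]}
        per_patient[pid] = per_patient.get(pid, set()) | det
    totals = {"relapse": 0, "no-relapse": 0}
    positive = {"relapse": 0, "no-relapse": 0}
    for pid, detected in per_patient.items():
        if pid not in labels:
            if allow_unknown:
                continue
            raise ValueError(f"patient {pid} has no relapse label")
        group = labels[pid]
        if group not in totals:
            raise ValueError(f"bad label {group!r} for patient {pid}")
        totals[group] += 1
        if len(detected) >= k:
            positive[group] += 1
    return {
        g: (positive[g] / totals[g]) if totals[g] else float("nan") for g in totals
    }
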