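"""Stratified mutation-frequency tables and cohort contingency tests.

Covers the descriptive and inferential statistics run on the combined
discovery + validation glioma cohort: per-gene mutation frequencies
stratified by WHO grade and pediatric/adult age group, association of
mutation status with tumor grade (high III+IV vs low II) and brain location
(hemispheric vs not), and pairwise mutual-exclusivity / co-occurrence tests
between driver genes. All tests delegate to the single two-sided Fisher
exact implementation in :mod:`glioburden.gene_burden` — one code path, one
oracle.

Samples whose status for the queried gene is ``unknown`` are excluded from
both numerator and denominator: denominators legitimately vary with assay
coverage, and imputation would fabricate counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from .core_model import AgeGroup, Arm, GeneStatus, Grade, Location, SampleMeta, ValidationError
from .gene_burden import ContingencyTable2x2, fisher_exact_two_sided

__all__ = [
    "StratumCount",
    "frequency_table",
    "frequency_table_to_frame",
    "grade_association",
    "location_association",
    "mutual_exclusivity",
    "Direction",
]


class StratumCount(NamedTuple):
    """Counts for one stratum: mutated, wildtype, total, percent mutated.

    ``percent`` is 100*mutated/total rounded to two decimals, or None for an
    empty stratum (rendered as an en dash in reports).
    """

    mutated: int
    wildtype: int
    total: int
    percent: float | None

    @classmethod
    def of(cls, mutated: int, wildtype: int) -> "StratumCount":
        total = mutated + wildtype
        pct = round(100.0 * mutated / total, 2) if total else None
        return cls(mutated, wildtype, total, pct)


def _status(sample: SampleMeta, gene: str) -> GeneStatus:
    if gene not in sample.gene_status:
        raise ValidationError(f"gene {gene!r} not tracked for sample {sample.sample_id!r}")
    return sample.gene_status[gene]


def _known(metadata: Sequence[SampleMeta], gene: str) -> list[SampleMeta]:
    if not any(gene in s.gene_status for s in metadata):
        raise ValidationError(f"gene {gene!r} absent from metadata")
    return [s for s in metadata if _status(s, gene) is not GeneStatus.UNKNOWN]


def frequency_table(
    metadata: Sequence[SampleMeta],
    gene: str,
) -> dict[tuple[str, str], StratumCount]:
    """Grade x age-group mutation-frequency table for one gene.

    Returns a mapping keyed by ``(grade, age_group)`` where ``age_group``
    ``"all"`` gives the per-grade total and ``("overall", "all")`` the whole
    cohort. Only samples with known status enter any cell; the result is
    invariant under metadata row order.
    """
    usable = _known(metadata, gene)
    table: dict[tuple[str, str], StratumCount] = {}

    def count(rows: Sequence[SampleMeta]) -> StratumCount:
        mut = sum(1 for s in rows if _status(s, gene) is GeneStatus.MUTATED)
        return StratumCount.of(mut, len(rows) - mut)

    for grade in (Grade.IV, Grade.III, Grade.II):
        in_grade = [s for s in usable if s.grade is grade]
        table[(grade.value, "all")] = count(in_grade)
        for ag in (AgeGroup.PEDIATRIC, AgeGroup.ADULT):
            table[(grade.value, ag.value)] = count([s for s in in_grade if s.age_group is ag])
    table[("overall", "all")] = count(usable)
    return table


def frequency_table_to_frame(table: Mapping[tuple[str, str], StratumCount]):
    """Frequency table as a tidy DataFrame; empty strata render percent '–'."""
    import pandas as pd

    rows = [
        (g, a, c.mutated, c.wildtype, c.total, "–" if c.percent is None else c.percent)
        for (g, a), c in table.items()
    ]
    return pd.DataFrame(rows, columns=["grade", "age_group", "mutated", "wildtype", "total", "percent"])


def grade_association(
    metadata: Sequence[SampleMeta],
    gene: str,
    high: frozenset[Grade] = frozenset({Grade.III, Grade.IV}),
    low: frozenset[Grade] = frozenset({Grade.II}),
) -> tuple[ContingencyTable2x2, float]:
    """Mutation status vs tumor grade group (high = III+IV, low = II).

    Returns the 2x2 table (rows = grade group, columns = mutated/wildtype)
    and the two-sided exact p-value. Either group being empty is an error.
    """
    usable = [s for s in _known(metadata, gene) if s.grade in high | low]
    hi = [s for s in usable if s.grade in high]
    lo = [s for s in usable if s.grade in low]
    if not hi or not lo:
        raise ValidationError("grade_association: a grade group is empty")
    t = ContingencyTable2x2(
        sum(1 for s in hi if _status(s, gene) is GeneStatus.MUTATED),
        sum(1 for s in hi if _status(s, gene) is GeneStatus.WILDTYPE),
        sum(1 for s in lo if _status(s, gene) is GeneStatus.MUTATED),
        sum(1 for s in lo if _status(s, gene) is GeneStatus.WILDTYPE),
    )
    return t, fisher_exact_two_sided(t)


def location_association(
    metadata: Sequence[SampleMeta],
    gene: str,
) -> tuple[ContingencyTable2x2, float]:
    """Mutation status vs brain location (hemispheric vs midline/other).

    Samples with location NA are excluded. A cohort with only one location
    group is an error.
    """
    usable = [s for s in _known(metadata, gene) if s.location is not Location.NA]
    hemi = [s for s in usable if s.location is Location.HEMISPHERIC]
    rest = [s for s in usable if s.location is not Location.HEMISPHERIC]
    if not hemi or not rest:
        raise ValidationError("location_association: need samples in both location groups")
    t = ContingencyTable2x2(
        sum(1 for s in hemi if _status(s, gene) is GeneStatus.MUTATED),
        sum(1 for s in hemi if _status(s, gene) is GeneStatus.WILDTYPE),
        sum(1 for s in rest if _status(s, gene) is GeneStatus.MUTATED),
        sum(1 for s in rest if _status(s, gene) is GeneStatus.WILDTYPE),
    )
    return t, fisher_exact_two_sided(t)


class Direction(enum.StrEnum):
    EXCLUSIVE = "exclusive"
    CO_OCCURRING = "co_occurring"
    NONE = "none"


def mutual_exclusivity(
    metadata: Sequence[SampleMeta],
    gene_a: str,
    gene_b: str,
) -> tuple[ContingencyTable2x2, float, Direction]:
    """Pairwise co-occurrence test between two driver genes.

    Builds the 2x2 of gene A status (rows) against gene B status (columns)
    over samples with known status for both, tests it two-sided, and calls
    the direction from the sign of observed minus expected double mutants
    (fewer than expected = mutually exclusive). Fewer than two usable
    samples is an error.
    """
    usable = [
        s
        for s in metadata
        if gene_a in s.gene_status
        and gene_b in s.gene_status
        and _status(s, gene_a) is not GeneStatus.UNKNOWN
        and _status(s, gene_b) is not GeneStatus.UNKNOWN
    ]
    if not any(gene_a in s.gene_status for s in metadata):
        raise ValidationError(f"gene {gene_a!r} absent from metadata")
    if not any(gene_b in s.gene_status for s in metadata):
        raise ValidationError(f"gene {gene_b!r} absent from metadata")
    if len(usable) < 2:
        raise ValidationError("mutual_exclusivity: fewer than 2 samples with both statuses known")
    both = a_only = b_only = neither = 0
    for s in usable:
        a_mut = _status(s, gene_a) is GeneStatus.MUTATED
        b_mut = _status(s, gene_b) is GeneStatus.MUTATED
        if a_mut and b_mut:
            both += 1
        elif a_mut:
            a_only += 1
        elif b_mut:
            b_only += 1
        else:
            neither += 1
    t = ContingencyTable2x2(both, a_only, b_only, neither)
    p = fisher_exact_two_sided(t)
    n = len(usable)
    expected_both = (both + a_only) * (both + b_only) / n
    if both < expected_both:
        direction = Direction.EXCLUSIVE
    elif both > expected_both:
        direction = Direction.CO_OCCURRING
    else:
        direction = Direction.NONE
    return t, p, direction
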