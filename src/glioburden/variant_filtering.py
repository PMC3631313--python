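"""Private/damaging filtering cascade defining candidate somatic mutations.

Without matched normal DNA, somatic status is approximated by *privacy*: a
variant is private when it is absent from the population databases (1000
Genomes, NHLBI exomes) and from every control exome. Private variants are
then screened for predicted functional impact: truncating classes (nonsense,
frameshift, splice-site) pass outright, while missense variants are removed
only when BOTH SIFT and PolyPhen-2 fail to call them damaging.
Synonymous and unclassified variants never qualify.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .core_model import Consequence, PolyphenCall, SiftCall, VariantRecord

__all__ = [
    "FilterRule",
    "FilterTrace",
    "is_private",
    "passes_damaging_filter",
    "is_truncating",
    "filter_cohort",
    "TRUNCATING_CLASSES",
]

#: Consequence classes expected to abolish protein function.
TRUNCATING_CLASSES = frozenset({
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.SPLICE_SITE,
})


class FilterRule(enum.StrEnum):
    """First rule a variant failed, in the fixed evaluation order."""

    POPULATION_DB = "population_db"
    CONTROL_EXOMES = "control_exomes"
    NOT_DAMAGING = "not_damaging"
    NOT_TRUNCATING = "not_truncating"
    NOT_CONSERVED = "not_conserved"
    NONE = "none"


@dataclass(frozen=True)
class FilterTrace:
    """Outcome of the filter cascade for one input variant."""

    index: int
    passed: bool
    failed_rule: FilterRule

    def __post_init__(self) -> None:
        if self.passed != (self.failed_rule is FilterRule.NONE):
            raise ValueError("passed must hold exactly when failed_rule is 'none'")


def is_private(v: VariantRecord) -> bool:
    """True iff the variant is absent from population databases and control exomes."""
    return not v.in_population_db and not v.in_control_exomes


def is_truncating(consequence: Consequence) -> bool:
    """True for nonsense, frameshift and splice-site variants."""
    return Consequence(consequence) in TRUNCATING_CLASSES


def passes_damaging_filter(v: VariantRecord) -> bool:
    """Predicted-impact screen.

    Truncating variants always pass (SIFT/PolyPhen-2 are missense predictors
    and cannot score them). A missense variant is removed only when both
    predictors are non-damaging (tolerated/benign/unknown) — one damaging
    call is enough to keep it. Synonymous and ``other`` never pass.
    """
    if is_truncating(v.consequence):
        return True
    if v.consequence is not Consequence.MISSENSE:
        return False
    both_non_damaging = v.sift is not SiftCall.DAMAGING and v.polyphen is not PolyphenCall.DAMAGING
    return not both_non_damaging


def filter_cohort(
    variants: Sequence[VariantRecord],
    mode: str = "all",
    require_conserved: bool = False,
) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Apply the full cascade; return kept variants and a trace per input.

    Rules are evaluated in fixed order — population database membership,
    control-exome membership, predicted impact, then (in truncating mode)
    consequence class — and the first failure is recorded. With
    ``require_conserved`` missense variants must additionally hit a highly
    conserved residue; this is off by default (conservation is reported, not
    required).

    The trace partitions the input: every variant is either kept or carries
    exactly one failed rule.
    """
    if mode not in ("all", "truncating"):
        raise ValueError(f"mode must be 'all' or 'truncating', got {mode!r}")
    kept: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    for i, v in enumerate(variants):
        rule = _first_failure(v, mode, require_conserved)
        if rule is FilterRule.NONE:
            kept.append(v)
        traces.append(FilterTrace(i, rule is FilterRule.NONE, rule))
    return kept, traces


def _first_failure(v: VariantRecord, mode: str, require_conserved: bool) -> FilterRule:
    if v.in_population_db:
        return FilterRule.POPULATION_DB
    if v.in_control_exomes:
        return FilterRule.CONTROL_EXOMES
    if not passes_damaging_filter(v):
        return FilterRule.NOT_DAMAGING
    if require_conserved and v.consequence is Consequence.MISSENSE and not v.conserved:
        return FilterRule.NOT_CONSERVED
    if mode == "truncating" and not is_truncating(v.consequence):
        return FilterRule.NOT_TRUNCATING
    return FilterRule.NONE
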