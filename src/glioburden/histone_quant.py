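"""Densitometry normalization and group comparison for H3K36me3 immunoblots.

H3K36me3 band intensities are normalized to total H3 within each (sample,
blot) pair, averaged across replicate blots per sample, and the per-sample
normalized ratios of SETD2-mutant versus triple-wildtype tumors are compared
with a two-tailed two-sample t-test (Welch by default).
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core_model import DensitometryTable, ValidationError

__all__ = ["normalized_ratios", "compare_groups", "TTestResult"]


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


def normalized_ratios(rows: Sequence[DensitometryTable]) -> tuple[dict[str, float], dict[str, str]]:
    """Per-sample mean of H3K36me3 / total-H3 across replicate blots.

    Each (sample, blot) contributes one ratio; blots missing a sample are
    simply skipped for it. Returns ``(ratios, groups)`` keyed by sample id.
    A sample appearing under two different group labels is an error, as is a
    non-positive total-H3 intensity (already rejected on construction).
    """
    if not rows:
        raise ValidationError("normalized_ratios: empty densitometry table")
    per_sample: dict[str, list[float]] = {}
    groups: dict[str, str] = {}
    for r in rows:
        if r.sample_id in groups and groups[r.sample_id] != r.group:
            raise ValidationError(
                f"sample {r.sample_id!r} assigned to both {groups[r.sample_id]!r} and {r.group!r}"
            )
        groups[r.sample_id] = r.group
        per_sample.setdefault(r.sample_id, []).append(r.h3k36me3 / r.h3_total)
    ratios = {sid: float(np.mean(vals)) for sid, vals in per_sample.items()}
    return ratios, groups


def compare_groups(
    ratios: Mapping[str, float],
    groups: Mapping[str, str],
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test between the two group labels.

    Welch's unequal-variance statistic by default; ``equal_var=True`` gives
    the pooled Student variant. Exactly two groups with at least two samples
    each are required. Identical groups return t = 0, p = 1.
    """
    labels = sorted(set(groups[s] for s in ratios))
    if len(labels) != 2:
        raise ValidationError(f"compare_groups: need exactly 2 groups, got {labels}")
    x = np.array([ratios[s] for s in sorted(ratios) if groups[s] == labels[0]])
    y = np.array([ratios[s] for s in sorted(ratios) if groups[s] == labels[1]])
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"compare_groups: each group needs >= 2 samples (got {len(x)} and {len(y)})"
        )
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # both groups constant and equal
        stat, p = 0.0, 1.0
    return TTestResult(stat, p)
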