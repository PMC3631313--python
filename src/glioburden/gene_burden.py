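"""Per-gene case–control carrier burden scan with exact testing and BH-FDR.

For each gene the cohort is reduced to a 2x2 table of carrier status
(>=1 qualifying variant) against cohort arm, compared with a two-sided
Fisher exact test and adjusted for multiple testing with the
Benjamini–Hochberg step-up procedure. Carrier counting — not allele or
variant counting — keeps the table margins equal to the cohort sizes, so
the case–control comparison implicitly absorbs each gene's background
mutability (gene length, local mutation rate).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_model import Arm, GeneBurdenResult, SampleMeta, ValidationError, VariantRecord

__all__ = [
    "ContingencyTable2x2",
    "gene_contingency",
    "fisher_exact_two_sided",
    "bh_fdr",
    "run_burden_scan",
]

#: Relative slack when comparing hypergeometric point probabilities, guarding
#: against float ties in the minimum-likelihood two-sided sum.
_EPS = 1e-7


class ContingencyTable2x2(NamedTuple):
    """2x2 counts: rows = tumor/control arm, columns = carrier/non-carrier."""

    a: int  # tumor carriers
    b: int  # tumor non-carriers
    c: int  # control carriers
    d: int  # control non-carriers


def gene_contingency(
    gene: str,
    kept_variants: Sequence[VariantRecord],
    metadata: Sequence[SampleMeta],
) -> ContingencyTable2x2:
    """Carrier 2x2 for one gene: samples with >=1 kept variant vs the rest.

    A sample with several kept variants in the gene counts once. Variants
    referencing a sample absent from the metadata are an error.
    """
    by_id = {s.sample_id: s for s in metadata}
    carriers: set[str] = set()
    for v in kept_variants:
        if v.sample_id not in by_id:
            raise ValidationError(f"variant references unknown sample {v.sample_id!r}")
        if v.gene == gene:
            carriers.add(v.sample_id)
    n_tumor = sum(1 for s in metadata if s.arm is Arm.TUMOR)
    n_control = len(metadata) - n_tumor
    a = sum(1 for sid in carriers if by_id[sid].arm is Arm.TUMOR)
    c = len(carriers) - a
    return ContingencyTable2x2(a, n_tumor - a, c, n_control - c)


def fisher_exact_two_sided(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p-value by direct enumeration.

    Conditioning on both margins, cell ``a`` follows a hypergeometric
    distribution; the two-sided p-value sums the point probabilities of all
    tables with the same margins whose probability does not exceed that of
    the observed table (the minimum-likelihood definition used by mainstream
    statistics tools). Degenerate margins (an all-zero row or column) leave a
    single feasible table, so p = 1.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValidationError(f"negative entry in 2x2 table {table!r}")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return 1.0
    ks = np.arange(lo, hi + 1)
    # hypergeom(M=n, n=c1 successes, N=r1 draws) is the null law of cell a
    pmf = hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _EPS)].sum())
    return min(p, 1.0)


def fisher_exact_one_sided(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> float:
    """One-sided (enrichment in tumors) exact p-value: P(X >= a) under the null."""
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValidationError(f"negative entry in 2x2 table {table!r}")
    n = a + b + c + d
    return float(min(1.0, hypergeom.sf(a - 1, n, a + c, a + b)))


def bh_fdr(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over ascending p, clipped to 1.
    ``m`` defaults to the number of p-values but may be larger, e.g. when
    the scan's gene universe exceeds the genes that reached testing; it can
    never be smaller. Ties in p receive identical q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValidationError(f"p-value {bad} outside (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"m={m} smaller than number of p-values ({p.size})")
    if p.size == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def run_burden_scan(
    variants: Sequence[VariantRecord],
    metadata: Sequence[SampleMeta],
    mode: str = "all",
    universe: int | None = None,
    alternative: str = "two-sided",
) -> list[GeneBurdenResult]:
    """Filter the cohort and test every gene; return results sorted by p.

    ``variants`` are raw annotated calls: the private/damaging cascade (and
    the truncating restriction when ``mode='truncating'``) is applied first.
    The gene universe for the FDR adjustment is every gene with at least one
    *kept* variant in tumors or controls; ``universe`` overrides the BH
    denominator m (>= number of tested genes) when the scan is meant to be
    interpreted against a larger exome-wide universe. Ties in p are broken
    by gene symbol, making the report deterministic.
    """
    from .variant_filtering import filter_cohort

    if mode not in ("all", "truncating"):
        raise ValidationError(f"mode must be 'all' or 'truncating', got {mode!r}")
    arms = {s.arm for s in metadata}
    if Arm.TUMOR not in arms or Arm.CONTROL not in arms:
        raise ValidationError("cohort must contain at least one tumor and one control sample")
    test = fisher_exact_two_sided if alternative == "two-sided" else fisher_exact_one_sided
    if alternative not in ("two-sided", "greater"):
        raise ValidationError(f"alternative must be 'two-sided' or 'greater', got {alternative!r}")

    kept, _ = filter_cohort(variants, mode=mode)
    genes = sorted({v.gene for v in kept})
    tables = {g: gene_contingency(g, kept, metadata) for g in genes}
    ps = [test(tables[g]) for g in genes]
    qs = bh_fdr(ps, m=universe) if genes else np.empty(0)
    rows = sorted(zip(genes, ps, qs), key=lambda t: (t[1], t[0]))
    return [
        GeneBurdenResult(g, *tables[g], p=p, q=float(q), rank=i + 1, mode=mode)
        for i, (g, p, q) in enumerate(rows)
    ]


def burden_results_to_frame(results: Iterable[GeneBurdenResult]):
    """Burden scan report as a DataFrame with the documented column order."""
    import pandas as pd

    return pd.DataFrame(
        [(r.gene, r.a, r.b, r.c, r.d, r.p, r.q, r.rank, r.mode) for r in results],
        columns=["gene", "a", "b", "c", "d", "p", "q", "rank", "mode"],
    )
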