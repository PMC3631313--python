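"""450K-style probe filtering, hierarchical clustering and consensus k-means.

The methylation stage mirrors the standard array workflow: drop unreliable
probes (cross-reactive, polymorphic binding region, sex chromosomes), keep
the most variable probes by standard deviation, then look for sample
structure two ways — average-linkage hierarchical clustering on Pearson
correlation distance, and resampled k-means consensus clustering with
CDF/delta-area model selection over a range of cluster numbers k.

Input betas are assumed already normalized (e.g. SWAN upstream). The
``quantile_normalize`` helper provided here is a plain per-sample quantile
normalization, NOT SWAN, and is clearly labeled as such.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_model import BetaMatrix, ConsensusResult, ValidationError

__all__ = [
    "filter_probes",
    "select_top_variable",
    "quantile_normalize",
    "hcluster_average_pearson",
    "consensus_kmeans",
    "cdf_delta_area",
    "SNP_MAF_CUTOFF",
    "SEX_CHROMS",
]

#: Probes whose binding region holds a variant at or above this minor-allele
#: frequency (2/120) are discarded.
SNP_MAF_CUTOFF = 2.0 / 120.0

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


# ---------------------------------------------------------------------------
# Probe filtering and selection
# ---------------------------------------------------------------------------

def filter_probes(bm: BetaMatrix) -> BetaMatrix:
    """Keep autosomal, non-cross-reactive probes without common binding SNPs.

    A probe is kept iff it is not cross-reactive, any known binding-region
    variant has minor-allele frequency below 2/120 (NA counts as no known
    variant), and its chromosome is not X or Y. Every probe must be
    annotated; the operation is idempotent.
    """
    if bm.probe_annotations is None:
        raise ValidationError("filter_probes: probe annotations required")
    ann = bm.probe_annotations
    missing = [p for p in bm.probe_ids if p not in ann.index]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} missing from annotations")
    kept = []
    for p in bm.probe_ids:
        row = ann.loc[p]
        maf = row["snp_maf"]
        if row["cross_reactive"]:
            continue
        if not (isinstance(maf, float) and math.isnan(maf)) and maf >= SNP_MAF_CUTOFF:
            continue
        if str(row["chrom"]) in SEX_CHROMS:
            continue
        kept.append(p)
    return bm.subset_probes(kept)


def select_top_variable(bm: BetaMatrix, n: int = 8000) -> BetaMatrix:
    """Keep the n most variable probes by across-sample standard deviation.

    SD uses the n-1 denominator; ties are broken lexicographically by probe
    id so selection is deterministic. Asking for more probes than exist
    returns all of them with a warning. Fewer than two samples leaves the SD
    undefined and is an error.
    """
    if n < 1:
        raise ValidationError(f"select_top_variable: n must be >= 1, got {n}")
    if bm.n_samples < 2:
        raise ValidationError("select_top_variable: need >= 2 samples for a standard deviation")
    sds = bm.beta.std(axis=1, ddof=1)
    if n > bm.n_probes:
        warnings.warn(
            f"requested top {n} probes but matrix has only {bm.n_probes}; returning all",
            stacklevel=2,
        )
        n = bm.n_probes
    order = sorted(range(bm.n_probes), key=lambda i: (-sds[i], bm.probe_ids[i]))
    chosen = sorted(order[:n])  # preserve original probe order within the subset
    return bm.subset_probes([bm.probe_ids[i] for i in chosen])


def quantile_normalize(bm: BetaMatrix) -> BetaMatrix:
    """Plain per-sample quantile normalization (NOT SWAN).

    Forces every sample column to the same distribution — the mean of the
    per-sample sorted beta vectors. Provided for exploratory use on betas
    that did not receive proper array normalization upstream; it is not a
    substitute for within-array methods that model probe-type chemistry.
    """
    ranks = np.argsort(np.argsort(bm.beta, axis=0), axis=0)
    mean_sorted = np.sort(bm.beta, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return BetaMatrix(list(bm.probe_ids), list(bm.sample_ids), out, bm.probe_annotations)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def _pearson_distance_matrix(x: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    sds = x.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(
                f"sample {sample_ids[j]!r} has zero variance over selected probes; "
                "Pearson distance undefined"
            )
    corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hcluster_average_pearson(bm: BetaMatrix, n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage (UPGMA) clustering on 1 - Pearson correlation.

    Samples are the items; distance between samples i, j is one minus the
    Pearson correlation of their beta columns, so samples equal up to a
    positive affine transform are at distance zero. Returns
    ``(labels, merge_tree)`` where labels are 1..n_clusters and the merge
    tree is a scipy linkage matrix. Deterministic for fixed input.
    """
    if bm.n_samples < 2:
        raise ValidationError("hcluster_average_pearson: need >= 2 samples")
    d = _pearson_distance_matrix(bm.beta, bm.sample_ids)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return labels, z


# ---------------------------------------------------------------------------
# Consensus k-means
# ---------------------------------------------------------------------------

def consensus_kmeans(
    bm: BetaMatrix,
    k_range: Sequence[int] = tuple(range(2, 11)),
    B: int = 1000,
    item_frac: float = 0.8,
    seed: int = 0,
    max_iter: int = 100,
) -> ConsensusResult:
    """Resampled k-means consensus clustering over a range of k.

    For each k, ``B`` resampling rounds each draw ``ceil(item_frac * n)``
    samples without replacement and partition the subsample with k-means
    (Euclidean distance on probe vectors, k-means++-style initialization,
    one restart, at most ``max_iter`` Lloyd iterations). The consensus entry
    for a sample pair is the fraction of rounds in which they co-clustered
    among rounds where both were drawn; the diagonal is 1. Final labels per
    k cut an average-linkage dendrogram of 1 - consensus at k clusters.
    Fully reproducible for a fixed seed.
    """
    from sklearn.cluster import KMeans

    n = bm.n_samples
    ks = sorted(int(k) for k in k_range)
    if not ks or ks[0] < 2:
        raise ValidationError("consensus_kmeans: k_range must contain integers >= 2")
    if n < max(ks) + 1:
        raise ValidationError(
            f"consensus_kmeans: need at least max(k)+1 = {max(ks) + 1} samples, have {n}"
        )
    if not (0.0 < item_frac <= 1.0):
        raise ValidationError(f"item_frac must be in (0, 1], got {item_frac}")
    x = bm.beta.T  # samples x probes
    n_draw = math.ceil(item_frac * n)
    rng = np.random.default_rng(seed)

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    for k in ks:
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(B):
            idx = np.sort(rng.choice(n, size=n_draw, replace=False))
            km_seed = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                        random_state=km_seed)
            assign = km.fit_predict(x[idx])
            both[np.ix_(idx, idx)] += 1.0
            for lab in range(k):
                members = idx[assign == lab]
                co[np.ix_(members, members)] += 1.0
        never = (both == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            i, j = np.argwhere(never)[0]
            raise ValidationError(
                f"samples {bm.sample_ids[i]!r} and {bm.sample_ids[j]!r} were never co-sampled "
                f"in {B} rounds; increase B"
            )
        with np.errstate(invalid="ignore"):
            m = np.where(both > 0, co / np.maximum(both, 1), 0.0)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        consensus[k] = m
        z = linkage(squareform(np.clip(1.0 - m, 0.0, None), checks=False), method="average")
        labels[k] = fcluster(z, t=k, criterion="maxclust")

    result = ConsensusResult(ks, list(bm.sample_ids), consensus, labels)
    if len(ks) >= 2:
        cdf_delta_area(result)  # fills A, delta, selected_k in place
    return result


def cdf_delta_area(
    cr: ConsensusResult,
    threshold: float = 0.025,
    grid_points: int = 101,
) -> tuple[dict[int, float], dict[int, float], int]:
    """Area under the consensus-value CDF and relative area gain per k.

    The empirical CDF of the upper-triangle consensus entries is evaluated
    on a fixed grid of ``grid_points`` points in [0, 1] and integrated by
    the trapezoid rule to give A(k). The relative gain is delta(2) = A(2)
    and delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2. ``selected_k`` is the
    smallest k after which delta drops below ``threshold`` (advisory: the
    consensus matrices and CDF plot remain the primary output). Results are
    stored on ``cr`` and returned.
    """
    ks = sorted(cr.k_values)
    if len(ks) < 2:
        raise ValidationError("cdf_delta_area: need at least two k values")
    grid = np.linspace(0.0, 1.0, grid_points)
    A: dict[int, float] = {}
    for k in ks:
        m = cr.consensus[k]
        iu = np.triu_indices_from(m, k=1)
        vals = m[iu]
        cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
        A[k] = float(np.trapezoid(cdf, grid))
    delta: dict[int, float] = {ks[0]: A[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        delta[k] = (A[k] - A[prev]) / A[prev] if A[prev] > 0 else 0.0
    selected = ks[-1]
    for prev, k in zip(ks, ks[1:]):
        if delta[k] < threshold:
            selected = prev
            break
    cr.A, cr.delta, cr.selected_k = A, delta, selected
    return A, delta, selected
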