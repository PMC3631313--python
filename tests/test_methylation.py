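"""Probe filtering, variable-probe selection, UPGMA and consensus k-means."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from glioburden import (
    BetaMatrix,
    BetaSimSpec,
    ValidationError,
    cdf_delta_area,
    consensus_kmeans,
    filter_probes,
    hcluster_average_pearson,
    select_top_variable,
    simulate_beta_matrix,
)
from glioburden.core_model import ConsensusResult
from glioburden.methylation_consensus import SNP_MAF_CUTOFF, quantile_normalize


def annotated_matrix(chroms, cross, mafs, n_samples=4, seed=0):
    n = len(chroms)
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:05d}" for i in range(n)]
    ann = pd.DataFrame({"chrom": chroms, "cross_reactive": cross, "snp_maf": mafs},
                       index=probes)
    ann.index.name = "probe_id"
    return BetaMatrix(probes, [f"s{j}" for j in range(n_samples)],
                      rng.uniform(0.1, 0.9, (n, n_samples)), ann)


class TestFilterProbes:
    def test_filter_rules(self):
        bm = annotated_matrix(
            chroms=["1", "chrX", "chrY", "2", "3", "4"],
            cross=[False, False, False, True, False, False],
            mafs=[np.nan, np.nan, np.nan, np.nan, 0.3, SNP_MAF_CUTOFF - 1e-9],
        )
        kept = filter_probes(bm)
        # chrX/chrY removed, cross-reactive removed, maf >= 2/120 removed,
        # autosomal clean probes kept (NA and sub-threshold maf both pass)
        assert kept.probe_ids == ["cg00000", "cg00005"]

    def test_idempotent(self):
        bm = annotated_matrix(["1", "chrX", "2"], [False, False, True],
                              [np.nan, np.nan, np.nan])
        once = filter_probes(bm)
        twice = filter_probes(once)
        assert twice.probe_ids == once.probe_ids

    def test_missing_annotation_rejected(self):
        bm = annotated_matrix(["1", "2"], [False, False], [np.nan, np.nan])
        bm.probe_annotations = bm.probe_annotations.iloc[:1]
        with pytest.raises(ValidationError, match="cg00001"):
            filter_probes(bm)

    def test_synthetic_manifest_count_matches_predicate_oracle(self):
        rng = np.random.default_rng(5)
        n = 300
        chroms = rng.choice(["1", "7", "chrX", "chrY"], n, p=[0.4, 0.4, 0.1, 0.1])
        cross = rng.random(n) < 0.1
        mafs = np.where(rng.random(n) < 0.5, np.nan, rng.uniform(0, 0.1, n))
        bm = annotated_matrix(list(chroms), list(cross), list(mafs))
        expected = sum(
            1 for i in range(n)
            if not cross[i] and chroms[i] not in ("chrX", "chrY")
            and (np.isnan(mafs[i]) or mafs[i] < SNP_MAF_CUTOFF)
        )
        assert filter_probes(bm).n_probes == expected


class TestSelectTopVariable:
    def test_constant_probe_ranks_last(self):
        bm = BetaMatrix(["flat", "vary"], ["s1", "s2", "s3"],
                        np.array([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]]))
        assert select_top_variable(bm, n=1).probe_ids == ["vary"]

    def test_selection_matches_sd_sort_oracle(self):
        rng = np.random.default_rng(7)
        beta = rng.uniform(0, 1, (20, 6))
        probes = [f"cg{i:03d}" for i in range(20)]
        bm = BetaMatrix(probes, [f"s{j}" for j in range(6)], beta)
        sds = beta.std(axis=1, ddof=1)
        oracle = {probes[i] for i in np.argsort(-sds)[:8]}
        assert set(select_top_variable(bm, n=8).probe_ids) == oracle

    def test_n_equal_probe_count_identity(self):
        bm = BetaMatrix(["a", "b"], ["s1", "s2"], np.array([[0.1, 0.2], [0.3, 0.4]]))
        assert select_top_variable(bm, n=2).probe_ids == ["a", "b"]

    def test_n_above_probe_count_warns(self):
        bm = BetaMatrix(["a", "b"], ["s1", "s2"], np.array([[0.1, 0.2], [0.3, 0.4]]))
        with pytest.warns(UserWarning, match="only 2"):
            assert select_top_variable(bm, n=5).n_probes == 2

    def test_single_sample_rejected(self):
        bm = BetaMatrix(["a"], ["s1"], np.array([[0.5]]))
        with pytest.raises(ValidationError, match="2 samples"):
            select_top_variable(bm, n=1)


class TestHierarchicalClustering:
    def test_affine_invariant_two_group_split(self):
        # within-group columns are positive affine transforms of each other:
        # Pearson distance 0 within groups, so the 2-cut is exact
        base1 = np.linspace(0.1, 0.9, 12)
        base2 = np.array([0.9, 0.1] * 6)
        cols = [base1, 0.5 * base1 + 0.05, base2, 0.8 * base2 + 0.1]
        beta = np.clip(np.column_stack(cols), 0, 1)
        bm = BetaMatrix([f"p{i}" for i in range(12)], ["a1", "a2", "b1", "b2"], beta)
        labels, _ = hcluster_average_pearson(bm, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_merge_tree_matches_brute_force_upgma(self):
        """Five samples against an O(n^3) average-linkage oracle with explicit
        pairwise-mean updates."""
        rng = np.random.default_rng(11)
        beta = rng.uniform(0.05, 0.95, (30, 5))
        bm = BetaMatrix([f"p{i}" for i in range(30)], list("abcde"), beta)
        _, z = hcluster_average_pearson(bm, 2)

        # oracle: naive UPGMA on the same distance matrix
        d = 1.0 - np.corrcoef(beta, rowvar=False)
        clusters = {i: [i] for i in range(5)}
        heights = []
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for i_pos, ki in enumerate(keys):
                for kj in keys[i_pos + 1:]:
                    dist = np.mean([d[x, y] for x in clusters[ki] for y in clusters[kj]])
                    if best is None or dist < best[0]:
                        best = (dist, ki, kj)
            dist, ki, kj = best
            heights.append(dist)
            new_key = max(clusters) + 1
            clusters[new_key] = clusters.pop(ki) + clusters.pop(kj)
        assert z[:, 2] == pytest.approx(heights, rel=1e-9)

    def test_duplicated_sample_merges_first_at_zero(self):
        rng = np.random.default_rng(3)
        beta = rng.uniform(0.1, 0.9, (20, 3))
        beta = np.column_stack([beta, beta[:, 0]])  # duplicate of first sample
        bm = BetaMatrix([f"p{i}" for i in range(20)], ["a", "b", "c", "a2"], beta)
        _, z = hcluster_average_pearson(bm, 2)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 3}

    def test_zero_variance_sample_rejected(self):
        beta = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        bm = BetaMatrix([f"p{i}" for i in range(10)], ["flat", "ok"], beta)
        with pytest.raises(ValidationError, match="flat"):
            hcluster_average_pearson(bm, 2)


class TestConsensusKmeans:
    def test_degenerate_single_run_gives_binary_co_membership(self, small_beta):
        bm, _ = small_beta
        cr = consensus_kmeans(bm, k_range=(2,), B=1, item_frac=1.0, seed=0)
        m = cr.consensus[2]
        assert set(np.unique(m)) <= {0.0, 1.0}
        # consensus equals the co-membership relation of the recovered labels
        co = (cr.labels[2][:, None] == cr.labels[2][None, :]).astype(float)
        assert (m == co).all()

    def test_separated_clusters_near_binary_consensus(self, small_beta):
        bm, labels = small_beta
        cr = consensus_kmeans(bm, k_range=(2, 3), B=60, seed=1)
        m = cr.consensus[2]
        assert (np.minimum(m, 1 - m) <= 0.02).all()
        assert adjusted_rand_score(labels, cr.labels[2]) == 1.0
        # with 2 true clusters the first delta dominates
        assert cr.delta[2] > cr.delta[3]

    def test_three_cluster_recovery(self):
        bm, labels = simulate_beta_matrix(BetaSimSpec(seed=2))
        cr = consensus_kmeans(bm, k_range=(3,), B=60, seed=2)
        assert adjusted_rand_score(labels, cr.labels[3]) >= 0.9

    def test_same_seed_bit_identical(self, small_beta):
        bm, _ = small_beta
        a = consensus_kmeans(bm, k_range=(2, 3), B=20, seed=7)
        b = consensus_kmeans(bm, k_range=(2, 3), B=20, seed=7)
        for k in (2, 3):
            assert (a.consensus[k] == b.consensus[k]).all()
            assert (a.labels[k] == b.labels[k]).all()
        assert a.A == b.A and a.delta == b.delta

    def test_matrix_invariants(self, small_beta):
        bm, _ = small_beta
        cr = consensus_kmeans(bm, k_range=(2, 4), B=25, seed=3)
        for k, m in cr.consensus.items():
            assert (m == m.T).all()
            assert (np.diag(m) == 1.0).all()
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_never_co_sampled_pair_advises_larger_B(self):
        bm, _ = simulate_beta_matrix(BetaSimSpec(n_samples=30, n_probes=40, k_true=2,
                                                 n_informative_probes=10, seed=4))
        with pytest.raises(ValidationError, match="increase B"):
            consensus_kmeans(bm, k_range=(2,), B=1, item_frac=0.3, seed=0)

    def test_too_few_samples_rejected(self, small_beta):
        bm, _ = small_beta
        with pytest.raises(ValidationError, match="samples"):
            consensus_kmeans(bm.subset_probes(bm.probe_ids), k_range=(30,), B=5, seed=0)


class TestCdfDeltaArea:
    @staticmethod
    def make_result(matrices):
        ks = sorted(matrices)
        n = matrices[ks[0]].shape[0]
        labels = {k: np.ones(n, dtype=int) for k in ks}
        return ConsensusResult(ks, [f"s{i}" for i in range(n)], matrices, labels)

    def test_all_zero_off_diagonal_gives_unit_area(self):
        m0 = np.eye(4)
        m1 = np.eye(4)
        cr = self.make_result({2: m0, 3: m1})
        A, _, _ = cdf_delta_area(cr)
        assert A[2] == pytest.approx(1.0)

    def test_hand_computed_area_and_delta(self):
        # k=2: all six upper-triangle entries 0.5 -> CDF is a unit step at 0.5;
        # trapezoid on the 101-point grid gives 0.5*0.01/2 + 0.5 = 0.505
        m_half = np.full((4, 4), 0.5)
        np.fill_diagonal(m_half, 1.0)
        # k=3: perfectly binary -> CDF steps at 0 (value 4/6) and 1
        m_bin = np.eye(4)
        m_bin[0, 1] = m_bin[1, 0] = 1.0
        m_bin[2, 3] = m_bin[3, 2] = 1.0
        cr = self.make_result({2: m_half, 3: m_bin})
        A, delta, _ = cdf_delta_area(cr)
        assert A[2] == pytest.approx(0.505)
        # binary CDF: 4/6 on [0,1) then 1 at t=1 -> area 4/6 + (1/6)*0.01/2
        assert A[3] == pytest.approx(4 / 6 + (1 - 4 / 6) * 0.01 / 2)
        assert delta[2] == pytest.approx(A[2])
        assert delta[3] == pytest.approx((A[3] - A[2]) / A[2])

    def test_more_binary_consensus_never_decreases_area(self, small_beta):
        bm, _ = small_beta
        cr = consensus_kmeans(bm, k_range=(2, 3, 4), B=30, seed=5)
        ks = cr.k_values
        assert all(cr.A[a] <= cr.A[b] + 1e-9 for a, b in zip(ks, ks[1:]))


def test_quantile_normalize_equalizes_sample_distributions():
    rng = np.random.default_rng(0)
    beta = np.column_stack([rng.beta(2, 5, 50), rng.beta(5, 2, 50), rng.beta(1, 1, 50)])
    bm = BetaMatrix([f"p{i}" for i in range(50)], ["a", "b", "c"], beta)
    out = quantile_normalize(bm)
    for j in range(1, 3):
        assert np.sort(out.beta[:, 0]) == pytest.approx(np.sort(out.beta[:, j]))
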