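"""Core islet predictor: geometric model, clustering, p-values, chunk merge."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgislet.errors import ComputeError, ConfigurationError
from cpgislet.predict import (
    CandidateCluster,
    GeometricModel,
    cluster_pvalue,
    cluster_sites,
    fit_geometric_model,
    geometric_pmf,
    merge_chunk_clusters,
    predict_islets,
    write_islet_bed,
)
from cpgislet.sequence import CpGSiteList, extract_cpg_sites
from cpgislet.simulate import ClusterSpec, generate_genome

from conftest import brute_force_clusters, random_site_list


def model(p: float) -> GeometricModel:
    return GeometricModel(chrom="chrT", p=p, effective_length=1000, n_cpg=int(1000 * p))


class TestGeometricModel:
    def test_p_is_cpg_count_over_length(self, chrom):
        seq = chrom("ACGTAAAAAT" * 10)  # 10 CpGs, 100 bases, no N
        m = fit_geometric_model(extract_cpg_sites(seq), seq)
        assert m.p == pytest.approx(0.1)

    def test_n_bases_excluded_from_denominator(self, chrom):
        seq = chrom("ACGTAAAAAT" * 10 + "N" * 20)  # 10 CpGs, length 120, 20 Ns
        m = fit_geometric_model(extract_cpg_sites(seq), seq)
        assert m.effective_length == 100
        assert m.p == pytest.approx(10 / 100)

    def test_fewer_than_two_sites_is_error(self, chrom):
        seq = chrom("ACGTTTTT")
        with pytest.raises(ComputeError):
            fit_geometric_model(extract_cpg_sites(seq), seq)

    @pytest.mark.parametrize("p,d,expected", [(0.5, 1, 0.5), (0.5, 3, 0.125), (0.2, 2, 0.16)])
    def test_pmf_closed_form(self, p, d, expected):
        assert geometric_pmf(d, model(p)) == pytest.approx(expected)

    def test_pmf_rejects_d_below_one(self):
        with pytest.raises(ValueError):
            geometric_pmf(0, model(0.5))

    @pytest.mark.parametrize("p,D", [(0.1, 1000), (0.5, 50), (0.01, 200)])
    def test_partial_sums_match_geometric_series(self, p, D):
        # sum_{d=1..D} (1-p)^(d-1) p == 1 - (1-p)^D, exactly (same fp ops)
        total = geometric_pmf(np.arange(1, D + 1), model(p)).sum()
        assert total == pytest.approx(1.0 - (1.0 - p) ** D, abs=1e-12)


class TestClusterSites:
    def test_hand_worked_example(self, site_list):
        clusters = cluster_sites(site_list([0, 2, 4, 100, 102]), d=12)
        assert [(c.start, c.end, c.n) for c in clusters] == [(0, 6, 3), (100, 104, 2)]
        assert clusters[0].gaps.tolist() == [1, 1]
        assert clusters[1].gaps.tolist() == [1]

    def test_gap_above_d_splits(self, site_list):
        assert cluster_sites(site_list([0, 20]), d=12) == []  # gap 19 > 12

    def test_gap_equal_d_is_inclusive(self, site_list):
        clusters = cluster_sites(site_list([0, 13]), d=12)  # gap 12 <= 12
        assert len(clusters) == 1 and clusters[0].n == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        pos = random_site_list(rng)
        d = int(rng.integers(1, 30))
        got = cluster_sites(CpGSiteList("c", pos), d=d, min_cpg=2)
        expected = brute_force_clusters(pos, d, 2)
        assert [c.cpg_positions.tolist() for c in got] == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_nesting_in_d(self, seed):
        """Every d-cluster's CpG set is contained in some d'-cluster (d' >= d)."""
        rng = np.random.default_rng(seed)
        pos = random_site_list(rng)
        sl = CpGSiteList("c", pos)
        for d, d2 in [(3, 12), (12, 50), (3, 50)]:
            coarse = [set(c.cpg_positions.tolist()) for c in cluster_sites(sl, d2, min_cpg=2)]
            for c in cluster_sites(sl, d, min_cpg=2):
                members = set(c.cpg_positions.tolist())
                assert any(members <= big for big in coarse)


class TestClusterPvalue:
    def test_n2_is_geometric_cdf(self, site_list):
        c = CandidateCluster(chrom="chrT", cpg_positions=np.array([0, 2]))  # total gap 1
        assert cluster_pvalue(c, model(0.5)) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("g", [1, 2, 5, 20])
    def test_n2_closed_form_any_gap(self, p, g):
        c = CandidateCluster(chrom="chrT", cpg_positions=np.array([0, 1 + g]))
        assert cluster_pvalue(c, model(p)) == pytest.approx(1 - (1 - p) ** g, rel=1e-12)

    @pytest.mark.parametrize("p", [0.05, 0.3])
    def test_n3_minimum_gap_equals_p_squared(self, p):
        c = CandidateCluster(chrom="chrT", cpg_positions=np.array([0, 2, 4]))  # gaps [1,1]
        assert cluster_pvalue(c, model(p)) == pytest.approx(p**2, rel=1e-12)

    @pytest.mark.parametrize("p,total", [(0.1, 2), (0.1, 5), (0.3, 8)])
    def test_n3_matches_exhaustive_enumeration(self, p, total):
        """Oracle: enumerate all (g1, g2) gap pairs with g1 + g2 <= total."""
        expected = sum(
            (1 - p) ** (g1 - 1) * p * (1 - p) ** (g2 - 1) * p
            for g1, g2 in itertools.product(range(1, total), repeat=2)
            if g1 + g2 <= total
        )
        c = CandidateCluster(chrom="chrT", cpg_positions=np.array([0, 2, 2 + total]))
        assert cluster_pvalue(c, model(p)) == pytest.approx(expected, rel=1e-10)

    def test_monotone_in_gap_sum(self):
        pvals = [
            cluster_pvalue(
                CandidateCluster(chrom="chrT", cpg_positions=np.array([0, 2, 2 + g])),
                model(0.1),
            )
            for g in range(2, 30)
        ]
        assert all(a < b for a, b in zip(pvals, pvals[1:]))

    def test_singleton_is_error(self):
        c = CandidateCluster(chrom="chrT", cpg_positions=np.array([5]))
        with pytest.raises(ValueError):
            cluster_pvalue(c, model(0.1))

    def test_calibration_against_discrete_attained_level(self):
        """On i.i.d. geometric background gaps, the fraction of n=2 clusters
        with p-value <= alpha matches the exact attained level (which is
        <= alpha because the gap distribution is discrete) within 3 s.e."""
        p, n_mc = 0.01, 100_000
        rng = np.random.default_rng(20240312)
        gaps = rng.geometric(p, size=n_mc)
        # n=2 p-value == 1-(1-p)^g (equivalence to cluster_pvalue is
        # asserted in test_n2_closed_form_any_gap); vectorized here
        # alphas chosen off the discrete atoms of the p-value distribution
        for alpha in (0.02, 0.05, 0.2):
            g_alpha = int(np.floor(np.log1p(-alpha) / np.log1p(-p)))
            attained = 1 - (1 - p) ** g_alpha
            assert attained <= alpha
            observed = np.mean(1 - (1 - p) ** gaps <= alpha)
            se = np.sqrt(attained * (1 - attained) / n_mc)
            assert abs(observed - attained) <= 3 * se


class TestMergeChunkClusters:
    def test_boundary_spanning_run_is_stitched(self):
        left = [CandidateCluster(chrom="c", cpg_positions=np.array([90, 95]))]
        right = [CandidateCluster(chrom="c", cpg_positions=np.array([95, 100]))]
        merged = merge_chunk_clusters(left, right, (90, 104), d=12)
        assert len(merged) == 1
        assert merged[0].cpg_positions.tolist() == [90, 95, 100]

    def test_duplicate_cluster_in_overlap_appears_once(self):
        dup = CandidateCluster(chrom="c", cpg_positions=np.array([50, 53]))
        merged = merge_chunk_clusters([dup], [dup], (40, 60), d=12)
        assert len(merged) == 1

    def test_different_chromosomes_rejected(self):
        a = CandidateCluster(chrom="c1", cpg_positions=np.array([0, 2]))
        b = CandidateCluster(chrom="c2", cpg_positions=np.array([50, 52]))
        with pytest.raises(ValueError):
            merge_chunk_clusters([a], [b], (40, 60), d=12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_chunked_and_merged_equals_single_pass(self, seed):
        """Split a random site list at a boundary with overlap d+2, cluster
        each side, merge — must equal clustering the full list directly."""
        rng = np.random.default_rng(seed)
        pos = random_site_list(rng, max_sites=60)
        if pos.size == 0:
            return
        d = int(rng.integers(1, 20))
        boundary = int(rng.integers(0, int(pos[-1]) + 2))
        ov = d + 2
        left_pos = pos[pos + 2 <= boundary + ov]
        right_pos = pos[pos >= boundary]
        sl = CpGSiteList("c", pos)
        left = cluster_sites(CpGSiteList("c", left_pos), d, min_cpg=1) if left_pos.size else []
        right = cluster_sites(CpGSiteList("c", right_pos), d, min_cpg=1) if right_pos.size else []
        merged = merge_chunk_clusters(left, right, (boundary, boundary + ov), d)
        merged = [c for c in merged if c.n >= 2]
        expected = cluster_sites(sl, d, min_cpg=2)
        assert [c.cpg_positions.tolist() for c in merged] == [
            c.cpg_positions.tolist() for c in expected
        ]


class TestPredictIslets:
    def test_planted_run_recovered_exactly(self):
        seq, truth = generate_genome(
            10_000, 0.005, [ClusterSpec(5_000, 10, 1)], seed=11
        )
        islets = predict_islets([seq], [12], alpha=1e-5)[12]
        planted = truth.planted_clusters[0]
        assert len(islets) == 1
        assert set(planted["positions"]) <= set(islets[0].cpg_positions.tolist())
        assert islets[0].p_value < 1e-5

    def test_workers_do_not_change_bed_output(self, tmp_path):
        seq, _ = generate_genome(40_000, 0.02, [ClusterSpec(20_000, 10, 2)], seed=4)
        outputs = []
        for workers in (1, 8):
            res = predict_islets([seq], [12], alpha=1e-3, workers=workers, chunk_size=5_000)
            path = tmp_path / f"w{workers}.bed"
            write_islet_bed(res[12], 12, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_prefilter_nesting_across_d(self):
        seq, _ = generate_genome(30_000, 0.02, seed=9)
        res = predict_islets([seq], [12, 50], alpha=1.0)  # alpha=1: no filtering
        coarse = [set(i.cpg_positions.tolist()) for i in res[50]]
        for isl in res[12]:
            members = set(isl.cpg_positions.tolist())
            assert any(members <= big for big in coarse)

    def test_empty_genome_and_bad_config(self):
        assert predict_islets([], [12]) == {12: []}
        with pytest.raises(ConfigurationError):
            predict_islets([], [])
        with pytest.raises(ConfigurationError):
            predict_islets([], [12], alpha=0)
        with pytest.raises(ConfigurationError):
            predict_islets([], [50], chunk_size=100)

    def test_bh_flag_is_more_conservative(self):
        seq, _ = generate_genome(30_000, 0.02, [ClusterSpec(15_000, 10, 2)], seed=2)
        plain = predict_islets([seq], [12], alpha=1e-3)[12]
        bh = predict_islets([seq], [12], alpha=1e-3, bh_correct=True)[12]
        keys = lambda lst: {(i.start, i.end) for i in lst}
        assert keys(bh) <= keys(plain)
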