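import networkx as nx
import numpy as np
import pytest

from glunet import metrics, networks, nulls
from glunet.io import ValidationError
from glunet.synthetic import generate_cohort

from conftest import make_cohort, plain_spec


class TestERSampling:
    def test_exact_edge_count_symmetric_zero_diag(self):
        rng = np.random.default_rng(0)
        for m in (0, 1, 50, 171):
            A = nulls.sample_er_adjacency(19, m, rng)
            assert int(A.sum()) // 2 == m
            np.testing.assert_array_equal(A, A.T)
            assert np.all(np.diag(A) == 0)

    def test_out_of_range_edge_count(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            nulls.sample_er_adjacency(5, 11, rng)


class TestErNullZ:
    def make_profile(self, stack, thresholds):
        return metrics.centrality_profile(stack, thresholds)

    def test_hub_flag_iff_mean_z_above_cutoff(self):
        rng = np.random.default_rng(1)
        A = nulls.sample_er_adjacency(20, 60, rng)
        while not networks.is_connected(A):
            A = nulls.sample_er_adjacency(20, 60, rng)
        stack = A[None]
        table = nulls.er_null_z(self.make_profile(stack, [0.5]), stack, n_null=100, seed=0)
        for m in nulls.CENTRALITY_METRICS:
            np.testing.assert_array_equal(table.hub[m], table.mean_z[m] > 1.96)

    def test_null_graph_count(self):
        rng = np.random.default_rng(2)
        A = nulls.sample_er_adjacency(15, 40, rng)
        while not networks.is_connected(A):
            A = nulls.sample_er_adjacency(15, 40, rng)
        stack = np.stack([A, A, A])
        table = nulls.er_null_z(
            self.make_profile(stack, [0.4, 0.5, 0.6]), stack, n_null=25, seed=0
        )
        assert table.n_null_graphs == 75

    def test_degenerate_complete_graph_warns_and_masks(self):
        n = 6
        A = np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8)
        stack = A[None]
        with pytest.warns(RuntimeWarning, match="degenerate"):
            table = nulls.er_null_z(
                self.make_profile(stack, [0.5]), stack, n_null=20, seed=0
            )
        # every null graph is the complete graph -> degree SD 0 -> z undefined
        assert np.all(np.isnan(table.z["degree"]))

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(3)
        A = nulls.sample_er_adjacency(15, 45, rng)
        while not networks.is_connected(A):
            A = nulls.sample_er_adjacency(15, 45, rng)
        stack = A[None]
        prof = self.make_profile(stack, [0.5])
        t1 = nulls.er_null_z(prof, stack, n_null=50, seed=99)
        t2 = nulls.er_null_z(prof, stack, n_null=50, seed=99)
        for m in nulls.CENTRALITY_METRICS:
            np.testing.assert_array_equal(t1.z[m], t2.z[m])

    def test_metric_subset(self):
        rng = np.random.default_rng(4)
        A = nulls.sample_er_adjacency(15, 45, rng)
        stack = A[None]
        prof = metrics.centrality_profile(stack, [0.5], require_connected=False)
        table = nulls.er_null_z(prof, stack, n_null=20, seed=0, metrics=("degree",))
        assert set(table.z) == {"degree"}


class TestTwoSidedPvalue:
    def test_plus_one_correction_worked_example(self):
        # 19 null draws all strictly below the real value -> p = 1/20
        null = np.linspace(0.0, 0.5, 19)
        assert nulls.two_sided_pvalue(1.0, null) == pytest.approx(0.05)

    def test_never_zero(self):
        assert nulls.two_sided_pvalue(10.0, np.zeros(999)) == pytest.approx(1 / 1000)

    def test_two_sided_uses_absolute_values(self):
        null = np.array([-5.0, 0.1, 0.2])
        assert nulls.two_sided_pvalue(1.0, null) == pytest.approx(2 / 4)


class TestPermuteGroups:
    def duplicate_group_cohort(self, n=8, r=5, seed=0):
        rng = np.random.default_rng(seed)
        block = 1.0 + 0.1 * rng.standard_normal((n, r))
        uptake = np.vstack([block, block])  # group b duplicates group a
        return make_cohort(
            uptake,
            genotype=["WT"] * n + ["HET"] * n,
            treatment=["SAL"] * (2 * n),
        )

    def test_identical_groups_zero_difference_p_one(self):
        cohort = self.duplicate_group_cohort()
        out = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "mean_degree",
            [0.3, 0.5], n_perm_per_threshold=50, seed=0,
        )
        assert out.real == pytest.approx(0.0)
        assert out.p == pytest.approx(1.0)

    def test_real_statistic_matches_direct_computation(self):
        spec = plain_spec(
            n_regions=8,
            n_per_group={("WT", "SAL"): 10, ("HET", "SAL"): 10},
            rcc_regions=frozenset(range(4)),
            rcc_corr=0.8,
            base_corr=0.3,
            seed=6,
        )
        cohort = generate_cohort(spec)
        grid = [0.3, 0.4]
        out = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "mean_degree",
            grid, n_perm_per_threshold=10, seed=1,
        )
        diffs = []
        for t in grid:
            per = []
            for g in (("WT", "SAL"), ("HET", "SAL")):
                R = np.corrcoef(cohort.group_uptake(*g), rowvar=False)
                A = networks.adjacency_at(R, t)
                per.append(A.sum() / A.shape[0])
            diffs.append(per[0] - per[1])
        assert out.real == pytest.approx(float(np.mean(diffs)), abs=1e-12)
        np.testing.assert_allclose(out.per_threshold_real, diffs, atol=1e-12)

    def test_evaluation_count(self):
        cohort = self.duplicate_group_cohort()
        out = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "clustering",
            [0.3, 0.4, 0.5], n_perm_per_threshold=40, seed=2,
        )
        assert out.n_evaluated == 120
        assert out.n_perm_per_threshold == 40

    def test_reproducible_with_seed(self):
        cohort = self.duplicate_group_cohort(seed=5)
        a = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "mean_degree",
            [0.4], n_perm_per_threshold=30, seed=7,
        )
        b = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "mean_degree",
            [0.4], n_perm_per_threshold=30, seed=7,
        )
        np.testing.assert_array_equal(a.null, b.null)
        assert a.p == b.p

    def test_region_z_statistic(self):
        spec = plain_spec(
            n_regions=8,
            n_per_group={("WT", "SAL"): 12, ("HET", "SAL"): 12},
            rcc_regions=frozenset(range(4)),
            rcc_corr=0.85,
            base_corr=0.2,
            seed=4,
        )
        cohort = generate_cohort(spec)
        out = nulls.permute_groups(
            cohort, ("WT", "SAL"), ("HET", "SAL"), "degree_z",
            [0.4], n_perm_per_threshold=20, seed=3, region=0, er_null_size=50,
        )
        assert np.isfinite(out.real)
        assert 0 < out.p <= 1

    def test_z_statistic_requires_region(self):
        cohort = self.duplicate_group_cohort()
        with pytest.raises(ValidationError, match="region"):
            nulls.permute_groups(
                cohort, ("WT", "SAL"), ("HET", "SAL"), "degree_z",
                [0.4], n_perm_per_threshold=5, seed=0,
            )

    def test_unknown_statistic(self):
        cohort = self.duplicate_group_cohort()
        with pytest.raises(ValidationError, match="unknown statistic"):
            nulls.permute_groups(
                cohort, ("WT", "SAL"), ("HET", "SAL"), "nope",
                [0.4], n_perm_per_threshold=5, seed=0,
            )


class TestRichClub:
    def test_phi_matches_networkx(self):
        G = nx.gnm_random_graph(20, 60, seed=0)
        A = nx.to_numpy_array(G, dtype=np.uint8)
        ref = nx.rich_club_coefficient(G, normalized=False)
        for k, phi_ref in ref.items():
            mine = nulls.rich_club_phi(A, k)
            if mine is not None:
                assert mine == pytest.approx(phi_ref), k

    def test_complete_graph_empty_core(self):
        n = 8
        A = np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8)
        res = nulls.rich_club_core(A[None], [0.5], n_rewire_null=20, seed=0)
        assert res.rcc == frozenset()
        for levels in res.per_threshold:
            for lv in levels:
                assert lv.phi == pytest.approx(1.0)
                assert lv.phi_norm == pytest.approx(1.0)

    def test_clique_plus_pendant_trees_recovers_clique(self):
        # 5-clique (nodes 0..4), each carrying a 2-node pendant chain.
        # (With single degree-1 pendants instead, the degree sequence forces
        # the clique in *every* rewiring, so a degree-preserving null can
        # never flag it; chains leave the null slack.)
        n = 15
        A = np.zeros((n, n), dtype=np.uint8)
        for i in range(5):
            for j in range(i + 1, 5):
                A[i, j] = A[j, i] = 1
        for c in range(5):
            mid, leaf = 5 + 2 * c, 6 + 2 * c
            A[c, mid] = A[mid, c] = 1
            A[mid, leaf] = A[leaf, mid] = 1
        res = nulls.rich_club_core(A[None], [0.5], n_rewire_null=300, seed=1)
        assert res.k_star == [2]
        assert res.rcc == frozenset(range(5))

    def test_reproducible(self):
        G = nx.gnm_random_graph(15, 40, seed=3)
        A = nx.to_numpy_array(G, dtype=np.uint8)
        r1 = nulls.rich_club_core(A[None], [0.5], n_rewire_null=50, seed=9)
        r2 = nulls.rich_club_core(A[None], [0.5], n_rewire_null=50, seed=9)
        assert r1.rcc == r2.rcc
        assert [lv.p for lv in r1.per_threshold[0]] == [
            lv.p for lv in r2.per_threshold[0]
        ]

    def test_flagged_as_approximate(self):
        n = 6
        A = np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8)
        res = nulls.rich_club_core(A[None], [0.5], n_rewire_null=5, seed=0)
        assert res.approximate
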