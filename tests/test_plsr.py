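import numpy as np
import pytest

from glunet import plsr
from glunet.io import ValidationError, default_regions
from glunet.plsr import RankError, VIPTable
from glunet.synthetic import generate_cohort

from conftest import make_cohort, plain_spec


def orthogonal_toy_cohort():
    """Region 0 = response; region 1 = identical signal; region 2 orthogonal."""
    y = np.array([1.0, -1.0, 1.0, -1.0])
    x2 = np.array([1.0, 1.0, -1.0, -1.0])
    uptake = 2.0 + 0.1 * np.column_stack([y, y, x2])
    return make_cohort(uptake, genotype=["WT"] * 4, treatment=["SAL"] * 4)


class TestPLSFit:
    def test_exact_predictor_dominates(self):
        cohort = orthogonal_toy_cohort()
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=1)
        np.testing.assert_allclose(np.abs(model.weights[:, 0]), [1.0, 0.0], atol=1e-12)
        assert model.ssy[0] == pytest.approx(1.0)

    def test_weights_proportional_to_correlations_one_component(self):
        rng = np.random.default_rng(0)
        uptake = 1.0 + 0.1 * rng.standard_normal((20, 6))
        cohort = make_cohort(uptake, genotype=["WT"] * 20, treatment=["SAL"] * 20)
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=1)
        R = np.corrcoef(uptake, rowvar=False)
        corrs = R[0, 1:]
        ref = corrs / np.linalg.norm(corrs)
        np.testing.assert_allclose(model.weights[:, 0], ref, atol=1e-10)

    def test_explained_variance_non_decreasing(self):
        rng = np.random.default_rng(1)
        uptake = 1.0 + 0.1 * rng.standard_normal((15, 8))
        cohort = make_cohort(uptake, genotype=["WT"] * 15, treatment=["SAL"] * 15)
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 2, n_components=4)
        assert np.all(model.ssy >= -1e-12)
        ev = model.explained_variance
        assert np.all(np.diff(ev) >= -1e-12)
        assert ev[-1] <= 1 + 1e-9

    def test_matches_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        uptake = 1.0 + 0.1 * rng.standard_normal((16, 7))
        cohort = make_cohort(uptake, genotype=["WT"] * 16, treatment=["SAL"] * 16)
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 3, n_components=3)
        X = uptake[:, [j for j in range(7) if j != 3]]
        y = uptake[:, 3]
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ref = PLSRegression(n_components=3, scale=False).fit(Xs, ys)
        for a in range(3):
            w_ref = ref.x_weights_[:, a]
            w = model.weights[:, a]
            sign = np.sign(w_ref @ w) or 1.0
            np.testing.assert_allclose(w, sign * w_ref, atol=1e-8)

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(3)
        uptake = 1.0 + 0.1 * rng.standard_normal((8, 3))
        cohort = make_cohort(uptake, genotype=["WT"] * 8, treatment=["SAL"] * 8)
        with pytest.raises(RankError):
            plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=3)  # p = 2

    def test_group_too_small(self):
        cohort = orthogonal_toy_cohort()
        with pytest.raises(ValidationError):
            plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=3)


class TestVIP:
    def test_worked_toy_sqrt2(self):
        cohort = orthogonal_toy_cohort()
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=1)
        v = plsr.vip(model)
        np.testing.assert_allclose(v, [np.sqrt(2.0), 0.0], atol=1e-10)

    def test_identical_predictors_all_unit_vip(self):
        y = np.array([1.0, -1.0, 2.0, -2.0, 0.5])
        uptake = 3.0 + 0.1 * np.column_stack([y, y, y, y])
        cohort = make_cohort(uptake, genotype=["WT"] * 5, treatment=["SAL"] * 5)
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 0, n_components=1)
        np.testing.assert_allclose(plsr.vip(model), 1.0, atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_mean_square_identity(self, n_components):
        rng = np.random.default_rng(n_components)
        uptake = 1.0 + 0.1 * rng.standard_normal((14, 9))
        cohort = make_cohort(uptake, genotype=["WT"] * 14, treatment=["SAL"] * 14)
        model = plsr.plsr_fit(cohort, ("WT", "SAL"), 4, n_components=n_components)
        v = plsr.vip(model)
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-9)
        assert np.all(v >= 0)


class TestJackknife:
    def make_group(self, n, seed=0, edge=0.8):
        spec = plain_spec(
            n_regions=10,
            n_per_group={("WT", "SAL"): n},
            planted_edges={(0, 1): edge},
            base_corr=0.1,
            seed=seed,
        )
        return generate_cohort(spec)

    def test_ci_brackets_point_estimate(self):
        table = plsr.vip_jackknife(self.make_group(12), ("WT", "SAL"), 0, 2)
        assert np.all(table.ci_lower <= table.vip + 1e-12)
        assert np.all(table.vip <= table.ci_upper + 1e-12)
        assert np.all(table.ci_lower >= 0)
        np.testing.assert_array_equal(table.significant, table.ci_lower > 1.0)

    def test_planted_edge_flagged(self):
        hits = 0
        for seed in range(10):
            table = plsr.vip_jackknife(self.make_group(12, seed), ("WT", "SAL"), 0, 2)
            hits += bool(table.significant[table.targets.index(1)])
        assert hits >= 8

    def test_se_shrinks_like_inverse_sqrt_n(self):
        ns = [8, 16, 32, 64]
        ses = []
        for n in ns:
            se = []
            for seed in range(4):
                t = plsr.vip_jackknife(
                    self.make_group(n, seed=100 + seed), ("WT", "SAL"), 0, 1
                )
                se.append(t.se[t.targets.index(1)])
            ses.append(np.mean(se))
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert -0.85 < slope < -0.25

    def test_group_too_small_for_jackknife(self):
        cohort = self.make_group(12)
        sub = cohort.subset(np.arange(12) < 3)
        with pytest.raises(ValidationError):
            plsr.vip_jackknife(sub, ("WT", "SAL"), 0, 1)


def fabricate_table(seed, targets, vips, spread=0.01, group=("WT", "SAL"), n=8, rng_seed=0):
    """VIPTable with controlled point estimates and tight replicates."""
    rng = np.random.default_rng(rng_seed)
    vips = np.asarray(vips, dtype=float)
    reps = vips[None, :] + spread * rng.standard_normal((n, len(vips)))
    rep_mean = reps.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((reps - rep_mean) ** 2, axis=0))
    lower = np.clip(vips - 1.96 * se, 0, None)
    upper = vips + 1.96 * se
    return VIPTable(
        seed_region=seed,
        group_label=group,
        targets=tuple(targets),
        vip=vips,
        se=se,
        ci_lower=lower,
        ci_upper=upper,
        replicates=reps,
        significant=lower > 1.0,
        n_components=2,
    )


class TestCompareAndClassify:
    def test_compare_with_itself_all_p_one(self):
        t = fabricate_table(0, (1, 2, 3), [2.0, 1.0, 0.5])
        raw, adj = plsr.compare_vip(t, t)
        np.testing.assert_allclose(adj, 1.0)

    def test_bonferroni_multiplies_and_caps(self):
        a = fabricate_table(0, tuple(range(1, 59)), np.ones(58), rng_seed=1)
        b = fabricate_table(0, tuple(range(1, 59)), np.ones(58), rng_seed=2)
        raw, adj = plsr.compare_vip(a, b)
        np.testing.assert_allclose(adj, np.minimum(raw * 58, 1.0))

    def test_mismatched_targets_rejected(self):
        a = fabricate_table(0, (1, 2), [1.0, 1.0])
        b = fabricate_table(0, (1, 3), [1.0, 1.0])
        with pytest.raises(ValidationError):
            plsr.compare_vip(a, b)

    def test_unknown_method_rejected(self):
        t = fabricate_table(0, (1,), [1.0])
        with pytest.raises(ValidationError, match="method"):
            plsr.compare_vip(t, t, method="bogus")

    def test_lost_rule(self):
        wt = fabricate_table(0, (1, 2), [2.0, 1.5], rng_seed=3)
        het = fabricate_table(0, (1, 2), [0.5, 1.5], group=("HET", "SAL"), rng_seed=4)
        labels = {c.target: c.label for c in plsr.classify_changes(wt, het)}
        assert labels[1] == "lost"
        assert labels[2] == "unchanged"

    def test_ci_pattern_failure_blocks_lost(self):
        # significant difference but both CI lower bounds above 1 -> unchanged
        wt = fabricate_table(0, (1,), [3.0], rng_seed=5)
        het = fabricate_table(0, (1,), [1.8], group=("HET", "SAL"), rng_seed=6)
        assert het.ci_lower[0] > 1.0
        labels = [c.label for c in plsr.classify_changes(wt, het)]
        assert labels == ["unchanged"]

    def test_gained_rule_mirrored(self):
        wt = fabricate_table(0, (1,), [0.4], rng_seed=7)
        het = fabricate_table(0, (1,), [1.9], group=("HET", "SAL"), rng_seed=8)
        labels = [c.label for c in plsr.classify_changes(wt, het)]
        assert labels == ["gained"]

    def test_nonsignificant_difference_is_unchanged(self):
        wt = fabricate_table(0, (1,), [1.8], spread=0.6, rng_seed=9)
        het = fabricate_table(0, (1,), [1.7], spread=0.6, group=("HET", "SAL"), rng_seed=10)
        labels = [c.label for c in plsr.classify_changes(wt, het)]
        assert labels == ["unchanged"]


class TestRestoration:
    def tables(self, drug_vip, drug_spread=0.01):
        wt = fabricate_table(0, (1, 2), [2.5, 1.2], rng_seed=11)
        het = fabricate_table(0, (1, 2), [0.5, 1.1], group=("HET", "SAL"), rng_seed=12)
        drug = fabricate_table(
            0, (1, 2), [drug_vip, 1.1], spread=drug_spread,
            group=("HET", "KET"), rng_seed=13,
        )
        return het, drug, wt

    def test_restored_when_all_clauses_hold(self):
        het, drug, wt = self.tables(drug_vip=2.5)
        out = plsr.classify_restoration(het, drug, wt)
        assert [c.target for c in out] == [1]
        assert out[0].label == "restored"

    def test_not_restored_when_still_absent(self):
        het, drug, wt = self.tables(drug_vip=0.5)
        assert plsr.classify_restoration(het, drug, wt) == []

    def test_not_restored_when_drug_differs_from_wt(self):
        # drug CI lower > 1 but VIP far above WT with tight replicates:
        # the equivalence clause fails
        het, drug, wt = self.tables(drug_vip=6.0)
        assert plsr.classify_restoration(het, drug, wt) == []

    def test_only_lost_targets_considered(self):
        het, drug, wt = self.tables(drug_vip=2.5)
        out = plsr.classify_restoration(het, drug, wt)
        assert all(c.target != 2 for c in out)
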