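import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from tumorhet import (ValidationError, chi2_independence, cluster_patients,
                      kruskal_by_group, kruskal_wallis, mosaic_residuals,
                      rank_sum_test)
from tumorhet.simulate import simulate_cluster_treatment_table

from oracles import rank_sum_p_bruteforce


class TestClusterPatients:
    def test_duplicated_archetypes_co_assigned(self):
        arch = np.array([[0.7, 0.1, 0.1, 0.05, 0.05],
                         [0.1, 0.7, 0.1, 0.05, 0.05],
                         [0.05, 0.05, 0.1, 0.7, 0.1],
                         [0.05, 0.05, 0.1, 0.1, 0.7]])
        vecs = pd.DataFrame(np.vstack([arch, arch]),
                            index=[f"P{i}" for i in range(8)])
        res = cluster_patients(vecs, 4)
        for i in range(4):
            assert res.groups[f"P{i}"] == res.groups[f"P{i + 4}"]
        assert res.groups.nunique() == 4

    def test_planted_dirichlet_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        centers = np.array([[30, 2, 2, 2, 2], [2, 30, 2, 2, 2],
                            [2, 2, 30, 2, 2], [2, 2, 2, 2, 30]], dtype=float)
        truth, vecs = [], []
        for i in range(12):
            g = i % 4
            truth.append(g)
            vecs.append(rng.dirichlet(centers[g]))
        res = cluster_patients(pd.DataFrame(vecs, index=[f"P{i}" for i in range(12)]), 4)
        assert adjusted_rand_score(truth, res.groups.to_numpy()) >= 0.9

    def test_single_group_and_too_many_groups(self):
        vecs = pd.DataFrame(np.eye(3), index=list("abc"))
        assert set(cluster_patients(vecs, 1).groups) == {1}
        with pytest.raises(ValidationError):
            cluster_patients(vecs, 4)

    def test_invariant_to_patient_order(self, rng):
        vecs = pd.DataFrame(rng.dirichlet(np.ones(5), 10),
                            index=[f"P{i}" for i in range(10)])
        a = cluster_patients(vecs, 3).groups
        b = cluster_patients(vecs.iloc[::-1], 3).groups
        # same partition, possibly different group numbers
        for p1 in vecs.index:
            for p2 in vecs.index:
                assert (a[p1] == a[p2]) == (b[p1] == b[p2])


class TestKruskal:
    def test_tiny_case_exact_permutation_enumeration(self):
        h, p_perm = kruskal_wallis([[1, 2], [3, 4]], method="permutation")
        # H = (12/20)*(2*(1.5-2.5)^2 + 2*(3.5-2.5)^2) = 2.4
        assert h == pytest.approx(2.4)
        # only the two extreme splits of {1,2,3,4} reach H = 2.4
        assert p_perm == pytest.approx(2 / 6)

    def test_identical_values_tie_degenerate_convention(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert h == 0 and p == 1

    def test_type_one_error_nominal(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 500
        for _ in range(reps):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_by_group_frame_and_empty_group_error(self):
        vecs = pd.DataFrame({"WT": [0.5, 0.6, 0.1, 0.2],
                             "Amp": [0.5, 0.4, 0.9, 0.8]},
                            index=[f"P{i}" for i in range(4)])
        groups = pd.Series([1, 1, 2, 2], index=vecs.index)
        out = kruskal_by_group(vecs, groups)
        assert set(out["category"]) == {"WT", "Amp"}
        assert (out["p_value"] <= 1).all()
        with pytest.raises(ValidationError):
            kruskal_by_group(vecs, pd.Series([1, 1, 1, 1], index=vecs.index))


class TestRankSum:
    def test_worked_example_exact(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 20)
        b = rng.normal(2, 1, 20)
        _, p = rank_sum_test(a, b)
        assert p < 0.01

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
    def test_exact_p_matches_enumeration_battery(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(rank_sum_p_bruteforce(a, b), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestChi2:
    def test_exact_independence_gives_zero(self):
        res = chi2_independence([[10, 10], [10, 10]])
        assert res.chi2 == 0 and res.p_overall == 1 and res.df == 1

    def test_worked_example_closed_form(self):
        res = chi2_independence([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(6.6667, abs=5e-5)
        assert (res.expected.to_numpy() == 15).all()

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValidationError):
            chi2_independence([[1, 2]])  # 1x2: df = 0
        with pytest.raises(ValidationError):
            chi2_independence([[0, 0], [1, 2]])  # all-zero row
        with pytest.raises(ValidationError):
            chi2_independence([[1.5, 2], [3, 4]])  # non-integer counts

    def test_margins_preserved_in_expected(self, rng):
        obs = rng.integers(1, 50, size=(3, 4))
        res = chi2_independence(obs)
        np.testing.assert_allclose(res.expected.sum(axis=1), obs.sum(axis=1), atol=1e-9)
        np.testing.assert_allclose(res.expected.sum(axis=0), obs.sum(axis=0), atol=1e-9)


class TestMosaic:
    def test_null_table_all_residuals_zero(self):
        res = mosaic_residuals([[10, 10], [10, 10]])
        assert (res.residuals.to_numpy() == 0).all()
        assert (res.p_per_cell.to_numpy() == 1).all()

    def test_worked_residual_and_per_cell_p(self):
        res = mosaic_residuals([[20, 10], [10, 20]])
        assert res.residuals.iloc[0, 0] == pytest.approx(1.2910, abs=5e-5)
        assert res.p_per_cell.iloc[0, 0] == pytest.approx(0.1967, abs=5e-5)
        # sign encodes direction: depleted cells are negative
        assert res.residuals.iloc[0, 1] < 0

    def test_residual_squares_sum_to_chi2(self, rng):
        for _ in range(20):
            obs = rng.integers(1, 60, size=(rng.integers(2, 5), rng.integers(2, 5)))
            res = mosaic_residuals(obs)
            assert np.nansum(res.residuals.to_numpy() ** 2) == pytest.approx(
                res.chi2, abs=1e-9)

    def test_per_cell_p_is_normal_tail(self, rng):
        obs = rng.integers(5, 40, size=(3, 3))
        res = mosaic_residuals(obs)
        expect = 2 * (1 - norm.cdf(np.abs(res.residuals.to_numpy())))
        np.testing.assert_allclose(res.p_per_cell.to_numpy(), expect, atol=1e-12)

    def test_agrees_with_chi2_independence(self, rng):
        obs = rng.integers(1, 30, size=(3, 4))
        a, b = chi2_independence(obs), mosaic_residuals(obs)
        assert (a.chi2, a.df, a.p_overall) == (b.chi2, b.df, b.p_overall)

    def test_relabeling_invariance(self, rng):
        obs = rng.integers(1, 30, size=(3, 4))
        base = mosaic_residuals(obs)
        perm_rows = mosaic_residuals(obs[::-1, :])
        assert perm_rows.chi2 == pytest.approx(base.chi2, abs=1e-9)
        assert perm_rows.p_overall == pytest.approx(base.p_overall, abs=1e-12)

    def test_accepts_label_table_input(self):
        labels, _ = simulate_cluster_treatment_table(
            2000, {"c1": 0.5, "c2": 0.5}, {"t1": 0.5, "t2": 0.5}, seed=1)
        res = mosaic_residuals(labels)
        assert res.observed.to_numpy().sum() == 2000

    def test_null_rejection_rate_nominal(self):
        rejections = 0
        reps = 1000
        for r in range(reps):
            labels, _ = simulate_cluster_treatment_table(
                1500, {"c1": 0.4, "c2": 0.35, "c3": 0.25},
                {"t1": 0.5, "t2": 0.5}, seed=50_000 + r)
            if mosaic_residuals(labels).p_overall < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
def test_bh_adjustment_monotone_and_bounded(pvals):
    from tumorhet import benjamini_hochberg

    adj = benjamini_hochberg(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-15)
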