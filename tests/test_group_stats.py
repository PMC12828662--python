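"""Permutation tests, BH-FDR (vs brute force), and demographics tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strokeconn as sc
from strokeconn.group_stats import (
    chi_square_2x2,
    fdr_bh,
    permutation_edge_test,
    permutation_test_matrix,
    two_sample_t,
)


def brute_force_bh(p, q):
    """Step-up definition applied literally: find the largest k with
    p_(k) <= k*q/m; reject those k, q_i = min over j>=rank(i) of
    m*p_(j)/j capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qvals = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    qvals = np.minimum(qvals, 1.0)
    out_q = np.empty(m)
    out_q[order] = qvals
    k = 0
    for idx in range(m):
        if ranked[idx] <= (idx + 1) * q / m:
            k = idx + 1
    flags = np.zeros(m, bool)
    flags[order[:k]] = True
    return out_q, flags


class TestPermutationTest:
    def test_reproducible_given_seed(self, rng):
        a = rng.standard_normal((12, 5))
        b = rng.standard_normal((15, 5))
        d1, p1 = permutation_test_matrix(a, b, n_perm=500, seed=3)
        d2, p2 = permutation_test_matrix(a, b, n_perm=500, seed=3)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(d1, d2)

    def test_delta_invariant_to_subject_order(self, rng):
        a = rng.standard_normal((12, 4))
        b = rng.standard_normal((10, 4))
        d1, _ = permutation_test_matrix(a, b, n_perm=200, seed=0)
        d2, _ = permutation_test_matrix(
            a[::-1], b[::-1], n_perm=200, seed=0
        )
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_planted_shift_attains_lower_bound(self, rng):
        a = rng.standard_normal((15, 1)) + 10.0
        b = rng.standard_normal((15, 1))
        delta, p = permutation_edge_test(a[:, 0], b[:, 0], n_perm=1000, seed=1)
        assert delta == pytest.approx(10.0, abs=1.5)
        assert p == pytest.approx(1 / 1001)

    def test_covariate_adjustment_removes_confound(self, rng):
        # group difference entirely mediated by a covariate
        n = 40
        cov = np.concatenate([np.zeros(n), np.ones(n)])
        y = 3.0 * cov + rng.standard_normal(2 * n) * 0.1
        delta_unadj, p_unadj = permutation_edge_test(
            y[:n], y[n:], n_perm=500, seed=2
        )
        delta_adj, p_adj = permutation_edge_test(
            y[:n], y[n:], covariates=cov[:, None], n_perm=500, seed=2,
        )
        assert abs(delta_adj) < abs(delta_unadj) / 10
        assert p_adj > 0.2

    def test_type_i_error_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 within binomial error."""
        rejections = 0
        trials = 0
        for rep in range(40):
            a = rng.standard_normal((15, 10))
            b = rng.standard_normal((15, 10))
            _, p = permutation_test_matrix(a, b, n_perm=400, seed=rep)
            rejections += (p <= 0.05).sum()
            trials += p.size
        assert 0.02 < rejections / trials < 0.08

    def test_null_p_values_superuniform(self, rng):
        """Empirical CDF of null p-values never exceeds alpha by more than
        Monte-Carlo error."""
        ps = []
        for rep in range(30):
            a = rng.standard_normal((10, 20))
            b = rng.standard_normal((10, 20))
            _, p = permutation_test_matrix(a, b, n_perm=200, seed=100 + rep)
            ps.append(p)
        ps = np.concatenate(ps)
        for alpha in (0.01, 0.05, 0.2):
            ecdf = (ps <= alpha).mean()
            assert ecdf <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / ps.size)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_edge_test(np.ones(1), rng.standard_normal(5))


class TestFdrBH:
    def test_all_tiny_p_all_significant(self):
        q, flags = fdr_bh(np.full(100, 0.001), 0.01)
        assert flags.all()

    def test_worked_example(self):
        q, flags = fdr_bh(np.array([0.001, 0.02, 0.9]), 0.05)
        np.testing.assert_allclose(q, [0.003, 0.03, 0.9], atol=1e-12)
        assert flags.tolist() == [True, True, False]

    def test_single_p_unchanged(self):
        q, flags = fdr_bh(np.array([0.5]), 0.05)
        assert q[0] == pytest.approx(0.5)
        assert not flags[0]

    def test_empty_input_empty_output(self):
        q, flags = fdr_bh(np.array([]), 0.05)
        assert q.size == 0 and flags.size == 0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=20),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_step_up(self, p, q_thr):
        p = np.array(p)
        q, flags = fdr_bh(p, q_thr)
        q_ref, flags_ref = brute_force_bh(p, q_thr)
        np.testing.assert_allclose(q, q_ref, atol=1e-10)
        assert flags.tolist() == flags_ref.tolist()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]), 0.05)


class TestCompareGroups:
    def test_row_count_and_family_sum(self, effect_cohort, seven):
        res = sc.compare_groups(effect_cohort, seven, n_perm=500, seed=5)
        assert len(res) == 378
        counts = sc.family_direction_counts(res)
        assert counts["total"].sum() == res["significant"].sum()

    def test_planted_pattern_directions_recovered(self, effect_cohort, seven):
        from strokeconn.synthetic import FIGURE_PATTERN_SIGNS

        res = sc.compare_groups(effect_cohort, seven, n_perm=1000, seed=5)
        sig = res[res["significant"]]
        assert len(sig) > 100
        planted = sig["family"].map(
            {f.value: s for f, s in FIGURE_PATTERN_SIGNS.items()}
        )
        observed = np.where(sig["delta"] > 0, 1, -1)
        assert (observed == planted).mean() >= 0.95

    def test_subgroup_consistency_with_symmetric_plant(self, seven):
        """Left- and right-lesion subgroups carry the same planted effect,
        so their significant-edge sets should agree on strong edges."""
        cohort = sc.generate_cohort(
            seven, 40, 30, T=200,
            effect=sc.figure_pattern_effect(0.25), seed=41,
        )
        left = sc.compare_groups(cohort, seven, n_perm=500, subgroup="left",
                                 seed=6)
        right = sc.compare_groups(cohort, seven, n_perm=500, subgroup="right",
                                  seed=6)
        sl = set(map(tuple, left[left.significant][["i", "j"]].to_numpy()))
        sr = set(map(tuple, right[right.significant][["i", "j"]].to_numpy()))
        assert sl and sr
        overlap = len(sl & sr) / min(len(sl), len(sr))
        assert overlap > 0.8

    def test_null_cohort_rarely_significant(self, null_cohort, seven):
        res = sc.compare_groups(null_cohort, seven, n_perm=500, seed=7)
        assert res["significant"].sum() <= 2

    def test_missing_module_edges_excluded_pairwise(self, seven):
        cohort = sc.generate_cohort(seven, 5, 5, T=80, seed=43)
        import dataclasses
        rec = cohort[0]
        ts = rec.module_ts.copy()
        ts.iloc[:, 3] = 1.0  # constant -> missing module for this subject
        cohort[0] = dataclasses.replace(rec, module_ts=ts)
        res = sc.compare_groups(cohort, seven, n_perm=200, seed=8)
        touching = res[(res.i == 3) | (res.j == 3)]
        # tested on remaining subjects, still reported
        assert touching["p"].notna().all()
        assert len(res) == 378


class TestDemographics:
    def test_table1_gender_chi_square(self):
        stat, p = chi_square_2x2(np.array([[38, 27], [42, 30]]))
        assert round(p, 3) == 0.988

    def test_identical_groups_statistic_zero(self):
        stat, p = chi_square_2x2(np.array([[20, 10], [20, 10]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # Pearson statistic n(ad-bc)^2 / (row and column marginals) = 20
        stat, p = chi_square_2x2(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))

    def test_t_test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(np.ones(5), np.ones(5))

    def test_demographics_table_structure(self, null_cohort):
        frame = sc.synthetic.cohort_to_frames(null_cohort)
        table = sc.demographics_tests(frame)
        assert set(table["variable"]) >= {"gender", "age", "MMSE"}
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
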