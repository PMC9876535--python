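import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plinet.stats import (
    average_over_epochs,
    eccentricity_ratio,
    fdr_bh,
    fit_lmm,
    grubbs_critical,
    grubbs_iterative,
    maxT_permutation,
    per_group_lmm,
    permutation_group_test,
)


class TestAverageOverEpochs:
    def test_simple_cases(self, rng):
        assert average_over_epochs([0.2, 0.4]) == pytest.approx(0.3)
        assert average_over_epochs([0.7]) == 0.7
        values = rng.uniform(0, 1, 30)
        assert average_over_epochs(values) == pytest.approx(sum(values) / 30)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_over_epochs([])


class TestGrubbs:
    def test_flags_single_gross_outlier(self):
        # G = 7.2/4.025 = 1.789 exceeds the n=5, alpha=0.05 critical 1.715
        values = [1.0, 1.0, 1.0, 1.0, 10.0]
        assert grubbs_iterative(values, alpha=0.05) == [4]
        assert grubbs_critical(5, 0.05) == pytest.approx(1.715, abs=0.005)

    def test_well_behaved_sample_keeps_everything(self):
        assert grubbs_iterative([1, 2, 3, 4, 5], alpha=0.05) == []

    def test_constant_vector_has_no_outliers(self):
        assert grubbs_iterative([2.0] * 6) == []

    def test_iterative_removal_of_two_outliers(self):
        # one gross and one moderate outlier; the second is masked until the
        # first is removed, which is exactly what the iteration handles
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1000.0, 10.0]
        flagged = grubbs_iterative(values, alpha=0.05)
        assert flagged == [6, 7]

    def test_never_removes_below_three(self):
        flagged = grubbs_iterative([0.0, 0.0, 100.0], alpha=0.5)
        assert len(flagged) <= 1  # stops once fewer than 3 would remain

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            grubbs_iterative([1.0, 2.0])


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        values = [0.1, 0.5, 0.9, 0.3]
        p = permutation_group_test(values, values, n_perm=500, seed=0)
        assert p > 0.95

    def test_exact_enumeration_of_separated_groups(self):
        a, b = [0.0] * 5, [10.0] * 5
        p = permutation_group_test(a, b, exact=True)
        assert p == pytest.approx(2 / math.comb(10, 5))

    def test_monte_carlo_approaches_exact(self):
        a = [0.1, 0.2, 0.3, 0.4, 0.5]
        b = [0.35, 0.45, 0.55, 0.65, 0.75]
        exact = permutation_group_test(a, b, exact=True)
        mc = permutation_group_test(a, b, n_perm=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_null_calibration(self, rng):
        # rejection rate at alpha=0.05 within binomial error under the null
        reps, alpha = 600, 0.05
        rejections = 0
        for k in range(reps):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            if permutation_group_test(a, b, n_perm=199, seed=k) < alpha:
                rejections += 1
        rate = rejections / reps
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se

    def test_label_swap_symmetry(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(10) + 1
        p_ab = permutation_group_test(a, b, n_perm=999, seed=7)
        p_ba = permutation_group_test(b, a, n_perm=999, seed=7)
        assert p_ab == pytest.approx(p_ba, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_test([], [1.0], n_perm=100)


class TestFdrBH:
    def test_step_up_hand_example(self):
        adjusted = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert adjusted == pytest.approx([0.05] * 5)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.33]) == pytest.approx([0.33])

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


def simulate_pre_post(
    rng,
    n_per_group=20,
    beta_interaction=0.0,
    subject_sd=1.0,
    residual_sd=0.5,
    covariates=True,
):
    rows = []
    sid = 0
    for group in ("control", "MCI"):
        for _ in range(n_per_group):
            subject = f"S{sid:03d}"
            sid += 1
            intercept = rng.normal(0, subject_sd)
            age = rng.normal(72, 6)
            edu = rng.normal(15, 2)
            gender = "female" if rng.random() < 0.88 else "male"
            for tp_code, timepoint in ((0, "pre"), (1, "post")):
                mean = intercept
                if group == "MCI" and tp_code == 1:
                    mean += beta_interaction
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "timepoint": timepoint,
                        "value": mean + rng.normal(0, residual_sd),
                        "age": age,
                        "gender": gender,
                        "education": edu,
                    }
                )
    return pd.DataFrame(rows)


class TestLmm:
    def test_interaction_recovered_within_three_se(self, rng):
        table = simulate_pre_post(rng, n_per_group=40, beta_interaction=0.5)
        fit = fit_lmm(table)
        est, se = fit.estimates["tp:grp"], fit.std_errors["tp:grp"]
        assert abs(est - 0.5) < 3 * se
        assert fit.random_intercept_var > 0
        assert 0 <= fit.p_values["tp:grp"] <= 1

    def test_balanced_no_covariates_reproduces_cell_means(self, rng):
        table = simulate_pre_post(rng, n_per_group=15, beta_interaction=0.8)
        fit = fit_lmm(table, covariates=False)
        cell = table.groupby(["group", "timepoint"])["value"].mean()
        contrast = (cell["MCI", "post"] - cell["MCI", "pre"]) - (
            cell["control", "post"] - cell["control", "pre"]
        )
        assert fit.estimates["tp:grp"] == pytest.approx(contrast, abs=1e-6)
        assert fit.estimates["tp"] == pytest.approx(
            cell["control", "post"] - cell["control", "pre"], abs=1e-6
        )

    def test_constant_response_raises(self, rng):
        table = simulate_pre_post(rng, n_per_group=5)
        table["value"] = 1.0
        with pytest.raises(ValueError):
            fit_lmm(table)

    def test_incomplete_subjects_dropped(self, rng):
        table = simulate_pre_post(rng, n_per_group=10)
        table = table.drop(table[(table.subject == "S000") & (table.timepoint == "post")].index)
        fit = fit_lmm(table)
        assert fit.n_subjects == 19

    def test_random_slope_option_fits_and_recovers_interaction(self, rng):
        table = simulate_pre_post(rng, n_per_group=30, beta_interaction=0.5)
        fit = fit_lmm(table, random_slope=True)
        assert abs(fit.estimates["tp:grp"] - 0.5) < 3 * max(
            fit.std_errors["tp:grp"], 0.1
        )

    def test_per_group_follow_up_recovers_timepoint_effect(self, rng):
        table = simulate_pre_post(rng, n_per_group=40, beta_interaction=0.6)
        fit_mci = per_group_lmm(table, "MCI")
        fit_ctl = per_group_lmm(table, "control")
        assert abs(fit_mci.estimates["tp"] - 0.6) < 3 * fit_mci.std_errors["tp"]
        assert abs(fit_ctl.estimates["tp"]) < 3 * fit_ctl.std_errors["tp"]


class TestEccentricityRatio:
    def test_identical_trees_give_unit_ratios(self):
        ecc = np.array([2, 3, 4, 3, 2])
        assert np.allclose(eccentricity_ratio(ecc, ecc), 1.0)

    def test_path_to_star_hand_computation(self, star9, path9):
        from plinet.mst import tree_metrics

        pre = tree_metrics(path9).eccentricity_per_vertex  # [8,7,6,5,4,5,6,7,8]
        post = tree_metrics(star9).eccentricity_per_vertex  # [1,2,2,...]
        ratios = eccentricity_ratio(pre, post)
        assert ratios[0] == pytest.approx(1 / 8)  # path end became the star centre
        assert ratios[4] == pytest.approx(2 / 4)  # path midpoint became a leaf
        assert np.all(ratios <= 1.0)

    def test_nonpositive_pre_guarded(self):
        with pytest.raises(ValueError):
            eccentricity_ratio(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestMaxT:
    def test_single_vertex_reduces_to_two_sample_permutation_test(self, rng):
        a = rng.standard_normal(12) + 1.2
        b = rng.standard_normal(12)
        x = np.concatenate([a, b])[:, None]
        groups = np.array(["g1"] * 12 + ["g2"] * 12)
        vmap = maxT_permutation(x, groups, n_perm=999, seed=3)
        # oracle: permutation distribution of |t| computed directly
        from scipy import stats as sps

        t_obs = sps.ttest_ind(a, b).statistic
        assert vmap.t_values[0] == pytest.approx(t_obs)
        rng2 = np.random.default_rng(99)
        pooled = x.ravel()
        count = 0
        for _ in range(999):
            perm = rng2.permutation(pooled)
            t = sps.ttest_ind(perm[:12], perm[12:]).statistic
            if abs(t) >= abs(t_obs):
                count += 1
        oracle_p = (1 + count) / 1000
        assert vmap.p_fwe[0] == pytest.approx(oracle_p, abs=0.05)

    def test_injected_effect_flagged_with_fwe_control(self, rng):
        n, v = 20, 16
        x = rng.standard_normal((2 * n, v))
        x[:n, 3] += 1.5  # strong group difference at one vertex
        groups = np.array(["a"] * n + ["b"] * n)
        vmap = maxT_permutation(x, groups, n_perm=999, seed=11)
        assert vmap.p_fwe[3] < 0.05
        assert np.argmax(np.abs(vmap.t_values)) == 3

    def test_p_values_in_unit_interval(self, rng):
        x = rng.standard_normal((10, 8))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        vmap = maxT_permutation(x, groups, n_perm=199, seed=0)
        assert np.all((vmap.p_fwe > 0) & (vmap.p_fwe <= 1))

    def test_two_groups_required(self, rng):
        x = rng.standard_normal((6, 4))
        with pytest.raises(ValueError):
            maxT_permutation(x, np.array(["a"] * 6), n_perm=199)
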