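import numpy as np
import pandas as pd
import pytest

from oracles import mannwhitney_oracle, wilcoxon_oracle
from suvkit.agreement import (
    bland_altman_median,
    least_squares_fit,
    mann_whitney_u,
    normality_gate,
    percentile,
    site_background_summary,
    size_stratified_summary,
    wilcoxon_signed_rank,
)
from suvkit.errors import DegenerateInputError


class TestLeastSquares:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = least_squares_fit(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_y_convention(self):
        r = least_squares_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r.slope == pytest.approx(0.0)
        assert r.r_squared == 0.0

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateInputError):
            least_squares_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 1.7 * x + rng.normal(0, 1, 20)
        r = least_squares_fit(x, y)
        # closed-form normal equations
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert r.slope == pytest.approx(beta[0], abs=1e-10)
        assert r.intercept == pytest.approx(beta[1], abs=1e-10)
        resid = y - A @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_bounds(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 5, 15)
            y = rng.uniform(0, 5, 15)
            assert 0.0 <= least_squares_fit(x, y).r_squared <= 1.0


class TestBlandAltman:
    def test_identical_inputs(self):
        v = [1.0, 2.0, 3.0, 4.0]
        ba = bland_altman_median(v, v)
        assert ba.median_diff_pct == 0.0
        assert (ba.loa_low_pct, ba.loa_high_pct) == (0.0, 0.0)

    def test_constant_ratio(self):
        spect = np.array([1.0, 2.5, 7.0, 10.0])
        ba = bland_altman_median(spect, 1.2 * spect)
        assert ba.median_diff_pct == pytest.approx(20.0)
        assert ba.loa_low_pct == pytest.approx(20.0)
        assert ba.loa_high_pct == pytest.approx(20.0)

    def test_percentile_interpolation_rule(self):
        # h = (n-1)p + 1 on {1..5}: 2.5th -> 1.1, 97.5th -> 4.9
        assert percentile([1, 2, 3, 4, 5], 2.5) == pytest.approx(1.1)
        assert percentile([1, 2, 3, 4, 5], 97.5) == pytest.approx(4.9)
        assert percentile([1, 2, 3, 4], 50.0) == pytest.approx(2.5)  # even-n median

    def test_rejects_non_positive_spect(self):
        with pytest.raises(ValueError):
            bland_altman_median([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])

    def test_loa_contain_94_to_96_pct(self, rng):
        for _ in range(5):
            d = rng.lognormal(0.2, 0.6, 400)
            spect = rng.uniform(5, 20, 400)
            ba = bland_altman_median(spect, spect * d)
            inside = np.mean(
                (ba.differences >= ba.loa_low_pct) & (ba.differences <= ba.loa_high_pct)
            )
            assert 0.94 <= inside <= 0.96

    def test_means_exposed_for_plotting(self):
        ba = bland_altman_median([2.0, 4.0, 8.0], [4.0, 6.0, 10.0])
        assert np.allclose(ba.means, [3.0, 5.0, 9.0])


class TestWilcoxon:
    def test_all_positive_no_ties(self):
        w, p, method = wilcoxon_signed_rank([0.3, 1.0, 2.1, 3.7, 4.2, 5.5])
        assert method == "exact"
        assert w == 21.0
        assert p == pytest.approx(2.0 / 64.0)

    def test_antisymmetric_pair(self):
        w, p, method = wilcoxon_signed_rank([2.5, -2.5])
        assert p == pytest.approx(1.0)

    def test_zeros_dropped(self):
        w1, p1, _ = wilcoxon_signed_rank([0.0, 0.3, 1.0, 2.1, 0.0, 3.7, 4.2, 5.5])
        w2, p2, _ = wilcoxon_signed_rank([0.3, 1.0, 2.1, 3.7, 4.2, 5.5])
        assert (w1, p1) == (w2, p2)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_exact_matches_enumeration(self, rng):
        for n in (3, 5, 8, 10):
            for _ in range(5):
                d = rng.normal(0.4, 1.0, n)
                d = np.where(d == 0, 0.123, d)
                w, p, method = wilcoxon_signed_rank(d)
                assert method == "exact"
                w_o, p_o = wilcoxon_oracle(d)
                assert w == pytest.approx(w_o)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_normal_approx_near_exact_at_n15(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.3, 1.0, 15)
        _, p_exact, m1 = wilcoxon_signed_rank(d)
        _, p_approx, m2 = wilcoxon_signed_rank(d, exact_max_n=0)
        assert (m1, m2) == ("exact", "normal")
        assert abs(p_exact - p_approx) < 0.005

    def test_branch_agreement_at_crossover(self, rng):
        # exact and approximate agree within 0.01 at the crossover n
        for _ in range(5):
            d = rng.normal(0.2, 1.0, 25)
            _, p_exact, _ = wilcoxon_signed_rank(d)
            _, p_approx, _ = wilcoxon_signed_rank(d, exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.01

    def test_monotone_transform_invariance(self, rng):
        spect = rng.uniform(1, 10, 12)
        pet = spect * rng.lognormal(0.1, 0.3, 12)
        # signed-rank on differences of log-transformed pairs == on log-ratio
        d1 = np.log(pet) - np.log(spect)
        d2 = np.exp(np.log(pet)) / np.exp(np.log(spect))  # same ordering, ratio scale
        _, p1, _ = wilcoxon_signed_rank(d1)
        _, p2, _ = wilcoxon_signed_rank(np.log(d2))
        assert p1 == pytest.approx(p2)


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, method = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert method == "exact"
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        u, p, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        for m, n in [(3, 3), (4, 5), (5, 5), (2, 7)]:
            a = rng.normal(0.5, 1.0, m)
            b = rng.normal(0.0, 1.0, n)
            u, p, method = mann_whitney_u(a, b)
            assert method == "exact"
            u_o, p_o = mannwhitney_oracle(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_one_sided_matches_enumeration(self, rng):
        a = rng.normal(1.0, 1.0, 5)
        b = rng.normal(0.0, 1.0, 6)
        u, p, _ = mann_whitney_u(a, b, alternative="greater")
        u_o, p_o = mannwhitney_oracle(a, b, alternative="greater")
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_shift_decreases_one_sided_p(self):
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        ps = []
        for shift in (0.0, 1.5, 3.0, 6.0):
            a = [x + shift + 0.01 for x in b]
            _, p, _ = mann_whitney_u(a, b, alternative="greater")
            ps.append(p)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_branch_agreement_at_crossover(self, rng):
        for _ in range(5):
            a = rng.normal(0.5, 1.0, 10)
            b = rng.normal(0.0, 1.0, 10)
            _, p_exact, _ = mann_whitney_u(a, b)
            _, p_approx, _ = mann_whitney_u(a, b, exact_max_n=0)
            assert abs(p_exact - p_approx) < 0.01

    def test_monotone_transform_invariance(self, rng):
        a = rng.uniform(0.5, 3.0, 8)
        b = rng.uniform(0.2, 2.5, 9)
        _, p1, _ = mann_whitney_u(a, b)
        _, p2, _ = mann_whitney_u(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestNormalityGate:
    # fixture checked against R's shapiro.test: W = 0.974582, p = 0.847068
    FIXTURE = [8.022, 9.264, 12.576, 10.388, 11.84, 11.154, 8.727, 11.084,
               9.367, 9.355, 10.194, 6.948, 12.384, 8.658, 12.001, 10.273,
               13.064, 8.68, 9.376, 10.676]

    def test_reference_cross_check(self):
        from scipy import stats

        w, p = stats.shapiro(self.FIXTURE)
        assert w == pytest.approx(0.97, abs=0.005)
        is_normal, p_gate = normality_gate(self.FIXTURE)
        assert is_normal
        assert p_gate == pytest.approx(0.847068, abs=1e-3)

    def test_heavy_tail_flagged(self):
        vals = [25.0, 0.828, 1.542, 1.127, 0.755, -0.146, 1.282, 1.074, 0.393,
                0.005, -0.362, -1.23, 1.226, -2.172, -0.37, 0.164, 0.86,
                1.762, 0.993, -0.292]
        is_normal, p = normality_gate(vals)
        assert not is_normal
        assert p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([2.0] * 10)

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


def paired_df(volumes, diffs_pct, site="spine", cls="benign"):
    volumes = np.asarray(volumes, float)
    diffs = np.asarray(diffs_pct, float)
    spect = np.full_like(volumes, 10.0)
    pet = spect * (1 + diffs / 100.0)
    return pd.DataFrame({
        "lesion_id": [f"L{i}" for i in range(len(volumes))],
        "volume_cm3": volumes,
        "site": site,
        "class": cls,
        "suv_max_spect": spect, "suv_max_pet": pet,
        "suv_peak_spect": spect, "suv_peak_pet": pet,
        "suv_mean_spect": spect, "suv_mean_pet": pet,
        "suv_mean_bg_spect": spect / 4, "suv_mean_bg_pet": pet / 4,
    })


class TestSizeStratifiedSummary:
    def test_volume_independent_differences(self):
        df = paired_df(np.arange(1, 13), np.full(12, 15.0))
        tab = size_stratified_summary(df)
        assert len(tab) == 4
        assert np.allclose(tab["suv_max_median_pct"], 15.0)

    def test_two_strata_hand_computed(self):
        df = paired_df(np.arange(1, 9), [10, 20, 30, 40, 50, 60, 70, 80])
        tab = size_stratified_summary(df, n_strata=2)
        assert list(tab["n"]) == [4, 4]
        assert tab["suv_max_median_pct"].tolist() == [25.0, 65.0]
        # IQR by the h = (n-1)p + 1 rule on {10,20,30,40}: q1=17.5, q3=32.5
        assert tab.loc[0, "suv_max_q1_pct"] == pytest.approx(17.5)
        assert tab.loc[0, "suv_max_q3_pct"] == pytest.approx(32.5)

    def test_231_lesions_split_58_58_58_57(self):
        df = paired_df(np.arange(231) + 1.0, np.zeros(231))
        tab = size_stratified_summary(df)
        assert list(tab["n"]) == [58, 58, 58, 57]

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            size_stratified_summary(paired_df([1.0, 2.0], [0, 0]))


class TestSiteBackgroundSummary:
    def test_constant_background_single_site(self):
        df = paired_df(np.arange(1, 7), np.zeros(6), site="skull")
        df["suv_mean_bg_spect"] = 2.0
        df["suv_mean_bg_pet"] = 2.0
        tab = site_background_summary(df)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["spect_median"] == 2.0
        assert row["spect_q3"] - row["spect_q1"] == 0.0

    def test_hand_computed_six_pairs(self):
        df = paired_df(np.arange(1, 7), np.zeros(6), site="pelvis")
        df["suv_mean_bg_spect"] = [4.0, 5.0, 4.5, 6.0, 5.5, 5.0]
        df["suv_mean_bg_pet"] = [4.6, 5.8, 5.0, 6.9, 6.2, 5.9]
        tab = site_background_summary(df)
        row = tab.iloc[0]
        assert row["spect_median"] == pytest.approx(5.0)
        assert row["pet_median"] == pytest.approx(5.85)
        assert row["diff_median"] == pytest.approx(np.median(
            np.array([4.6, 5.8, 5.0, 6.9, 6.2, 5.9]) - np.array([4.0, 5.0, 4.5, 6.0, 5.5, 5.0])
        ))
        assert 0 < row["wilcoxon_p"] < 0.1  # all six diffs positive: p = 2/64

    def test_site_ordering_preserved(self, rng):
        half = 8
        df = pd.concat([
            paired_df(np.arange(1, half + 1), np.zeros(half), site="spine"),
            paired_df(np.arange(1, half + 1), np.zeros(half), site="skull"),
        ], ignore_index=True)
        df.loc[df["site"] == "spine", "suv_mean_bg_spect"] = rng.uniform(5.5, 7.0, half)
        df.loc[df["site"] == "skull", "suv_mean_bg_spect"] = rng.uniform(1.5, 2.5, half)
        tab = site_background_summary(df).set_index("site")
        assert tab.loc["spine", "spect_median"] > tab.loc["skull", "spect_median"]

    def test_unknown_site_rejected(self):
        df = paired_df([1.0, 2.0, 3.0], [0, 0, 0], site="femur")
        with pytest.raises(ValueError):
            site_background_summary(df)
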