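import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from osteoload.stats import (
    GroupData,
    analysis_gate,
    descriptives,
    games_howell,
    levene,
    one_way_anova,
    paired_t,
    shapiro_wilk,
    weighted_group_mean,
    welch_anova,
)

DONOR_AGES = [41, 41, 50, 47, 34]
DONOR_BMIS = [28.4, 28.4, 29.3, 27.3, 26.5]


class TestDescriptives:
    def test_donor_roster_values(self):
        mean, sd = descriptives(DONOR_AGES, "population")
        assert mean == pytest.approx(42.6)
        assert sd == pytest.approx(5.54, abs=0.005)
        bmi_mean, bmi_sd = descriptives(DONOR_BMIS, "population")
        assert bmi_mean == pytest.approx(27.98)
        assert bmi_sd == pytest.approx(0.97, abs=0.005)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_sd_convention_relation(self, values):
        n = len(values)
        _, sd_pop = descriptives(values, "population")
        _, sd_samp = descriptives(values, "sample")
        assert sd_pop == pytest.approx(sd_samp * math.sqrt((n - 1) / n), abs=1e-9)

    def test_single_value(self):
        assert descriptives([3.0], "population") == (3.0, 0.0)
        with pytest.warns(UserWarning):
            _, sd = descriptives([3.0], "sample")
        assert math.isnan(sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            descriptives([])


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t([1, 2, 3.0], [1, 2, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_example(self):
        # differences (1,2,3,4): t = 2.5 / (1.2910/2) = 3.873, df 3
        r = paired_t([1, 2, 3, 4.0], [0, 0, 0, 0.0])
        assert r.statistic == pytest.approx(3.873, abs=1e-3)
        assert r.df == 3
        assert r.p_value == pytest.approx(0.0305, abs=5e-4)

    def test_incomplete_pairs_dropped(self):
        a = [1.0, 2.0, np.nan, 4.0, 5.0]
        b = [0.0, 0.5, 1.0, 2.0, np.nan]
        r = paired_t(a, b)
        assert r.df == 2  # 3 complete pairs

    def test_degenerate_constant_difference(self):
        r = paired_t([2, 3, 4.0], [1, 2, 3.0])
        assert r.p_value == 0.0
        assert "degenerate" in r.notes


class TestShapiroWilk:
    @pytest.mark.parametrize("n", [2, 5001])
    def test_size_limits(self, n):
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(n, dtype=float))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    @pytest.mark.parametrize("n", [5, 8, 12, 25, 60, 200])
    def test_matches_reference_implementation(self, n):
        rng = np.random.default_rng(n)
        for dist in (rng.standard_normal(n), rng.exponential(size=n)):
            mine = shapiro_wilk(dist)
            ref = sps.shapiro(dist)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-3)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=2e-3)

    def test_normal_data_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            shapiro_wilk(rng.standard_normal(50)).significant for _ in range(200)
        )
        assert rejections / 200 < 0.12  # near the nominal 5%

    def test_skewed_data_usually_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=50)).significant for _ in range(200)
        )
        assert rejections / 200 > 0.8


class TestLevene:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        r = levene([g, g, g])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_df_bookkeeping_minimal_groups(self):
        r = levene([[1.0, 2.0], [1.0, 3.0]])
        assert r.df == (1, 2)

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            levene(
                [rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                 rng.normal(0, math.sqrt(10), 15)]
            ).significant
            for _ in range(200)
        )
        assert rejections / 200 > 0.5

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, s, 12) for s in (1.0, 2.0, 0.5)]
        mine = levene(groups)
        ref = sps.levene(*groups, center="mean")
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestAnovaFamily:
    def test_identical_groups_welch(self):
        rng = np.random.default_rng(4)
        g = rng.normal(0, 1, 10)
        r = welch_anova([g, g + 0.0, g.copy()])
        assert r.statistic == pytest.approx(0.0, abs=1e-20)
        assert r.p_value == pytest.approx(1.0)

    def test_two_groups_equals_squared_welch_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 2, 9)
        r = welch_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(t**2, rel=1e-10)
        assert r.p_value == pytest.approx(p, rel=1e-8)

    def test_reduces_to_classic_for_equal_variance_and_n(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 20)
        groups = [base, base + 0.5, base + 1.0]  # identical variances, equal n
        rw = welch_anova(groups)
        rc = one_way_anova(groups)
        assert rw.statistic == pytest.approx(rc.statistic, rel=0.05)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])

    def test_matches_reference_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        for _ in range(5):
            groups = [
                rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), rng.integers(8, 20))
                for _ in range(3)
            ]
            mine = welch_anova(groups)
            df = pd.DataFrame(
                {"y": np.concatenate(groups),
                 "g": np.repeat([0, 1, 2], [len(g) for g in groups])}
            )
            ref = pg.welch_anova(dv="y", between="g", data=df)
            assert mine.statistic == pytest.approx(float(ref["F"][0]), rel=1e-8)
            assert mine.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)


class TestGamesHowell:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(8)
        g = rng.normal(0, 1, 10)
        r = games_howell([g, g.copy(), g.copy()])
        assert all(c.p_value > 1 - 1e-6 for c in r.pairwise)

    def test_k2_identity_with_welch_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 14), rng.normal(0.5, 2.5, 9)
        r = games_howell([a, b])
        _, p = sps.ttest_ind(a, b, equal_var=False)
        assert r.pairwise[0].p_value == pytest.approx(p, abs=5e-4)

    def test_matches_reference_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        groups = [rng.normal(m, s, n) for m, s, n in
                  ((0.0, 1.0, 15), (1.2, 2.0, 15), (0.5, 0.6, 12))]
        mine = games_howell(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups),
             "g": np.repeat([0, 1, 2], [len(g) for g in groups])}
        )
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        for c, (_, row) in zip(mine.pairwise, ref.iterrows()):
            assert c.p_value == pytest.approx(float(row["pval"]), abs=5e-4)
            assert c.difference == pytest.approx(float(row["mean_A"] - row["mean_B"]))


class TestGamesHowellFamilyWiseError:
    def test_fwe_under_null_at_most_nominal(self):
        """Under H0 (heteroscedastic, unequal n), the probability that any
        pairwise comparison rejects stays at or below the nominal level
        (within the binomial interval)."""
        rng = np.random.default_rng(21)
        reps = 400
        fwe = 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, 15), rng.normal(0, 2, 15), rng.normal(0, 3, 12)]
            r = games_howell(groups, compute_ci=False)
            fwe += any(c.p_value < 0.05 for c in r.pairwise)
        upper = 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / reps)
        assert fwe / reps <= upper, fwe / reps


class TestAnalysisGate:
    def test_heteroscedastic_goes_welch(self):
        rng = np.random.default_rng(11)
        groups = [
            GroupData("2", rng.normal(8.6, 1.0, 15)),
            GroupData("3", rng.normal(4.7, 1.0, 15)),
            GroupData("4", rng.normal(4.9, 0.1, 12)),
        ]
        res = analysis_gate(groups)
        assert res.branch == "welch"
        assert res.levene.significant
        assert res.post_hoc.pairwise

    def test_homoscedastic_goes_classic(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1.0, 15) for m in (0.0, 0.5, 1.0)]
        res = analysis_gate(groups)
        assert res.branch == "classic"
        assert not res.levene.significant
        assert "unadjusted" in res.post_hoc.name

    def test_gate_reports_normality_and_levene(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        res = analysis_gate(groups)
        assert len(res.normality) == 3
        log = res.log()
        assert "Levene" in log and "branch" in log


class TestWeightedMean:
    def test_reference_pooling(self):
        assert weighted_group_mean([8.57, 4.71, 4.88], [15, 15, 12]) == pytest.approx(
            6.14, abs=0.005
        )

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=6))
    def test_equal_ns_is_arithmetic_mean(self, means):
        assert weighted_group_mean(means, [7] * len(means)) == pytest.approx(
            float(np.mean(means)), abs=1e-9
        )

    def test_single_group(self):
        assert weighted_group_mean([3.3], [5]) == 3.3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_group_mean([1.0, 2.0], [3])
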