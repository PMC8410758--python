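"""Mixed-model fitting, LRT, t-tests, z-scores, ordinal summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from orgrowth import simulate, stats


def _final_week(seed=1, **kw):
    df = simulate.gen_morphometry(simulate.MorphoSimConfig(seed=seed, **kw))
    return df[df["week"] == 13.0].reset_index(drop=True)


class TestFitLMM:
    def test_zero_line_variance_collapses_to_ols(self):
        final = _final_week(seed=2, line_sd=0.0)
        fit = stats.fit_lmm(final, "log_area")
        assert fit.sigma_line <= 1e-3
        # ML loglik of the sigma_line = 0 model equals the OLS loglik
        y = np.log(final["area_mm2"].to_numpy())
        x = np.column_stack([np.ones(len(y)), (final["genotype"] == "case").to_numpy(float)])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        resid = y - x @ beta
        s2 = np.mean(resid**2)
        ll_ols = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)
        assert fit.genotype_effect == pytest.approx(beta[1], abs=1e-6)

    def test_matches_statsmodels_ml(self):
        import statsmodels.formula.api as smf

        final = _final_week(seed=1)
        data = final.assign(
            log_area=np.log(final["area_mm2"]),
            geno=(final["genotype"] == "case").astype(float),
        )
        sm_fit = smf.mixedlm("log_area ~ geno", data, groups=data["line_id"]).fit(reml=False)
        fit = stats.fit_lmm(final, "log_area")
        assert fit.genotype_effect == pytest.approx(sm_fit.params["geno"], abs=1e-6)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_duplication_changes_loglik_not_beta(self):
        final = _final_week(seed=5)
        fit1 = stats.fit_lmm(final, "log_area")
        doubled = pd.concat([final, final], ignore_index=True)
        fit2 = stats.fit_lmm(doubled, "log_area")
        assert fit2.loglik != pytest.approx(fit1.loglik, abs=1e-3)
        assert fit2.genotype_effect == pytest.approx(fit1.genotype_effect, abs=1e-4)

    def test_single_genotype_with_effect_requested_errors(self):
        final = _final_week(seed=1)
        only_control = final[final["genotype"] == "control"]
        with pytest.raises(ValueError):
            stats.fit_lmm(only_control, "log_area", include_genotype=True)

    def test_recovers_planted_log_fold(self):
        """Over 40 seeds the mean genotype coefficient sits within 2 SE of
        log(1.5)."""
        est = [
            stats.fit_lmm(
                _final_week(seed=s, line_sd=0.05, residual_sd=0.05), "log_area"
            ).genotype_effect
            for s in range(40)
        ]
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - np.log(1.5)) < 2 * se


class TestLRT:
    def test_identical_response_gives_chi2_zero(self):
        final = _final_week(seed=1)
        const = final.assign(area_mm2=2.0)
        res = stats.lrt_genotype(const, "log_area")
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_planted_effect_is_detected(self):
        chis = [
            stats.lrt_genotype(_final_week(seed=s), "log_area").chi2 for s in range(10)
        ]
        assert np.median(chis) > 3.84

    def test_nesting_loglik_order(self):
        final = _final_week(seed=8)
        full = stats.fit_lmm(final, "log_area", include_genotype=True)
        null = stats.fit_lmm(final, "log_area", include_genotype=False)
        assert full.loglik >= null.loglik - 1e-8


class TestDistributionTails:
    def test_chi2_tail_reference_points(self):
        # Printed LRT pairs: chi2(1) = 9.42 -> p ~ 0.002
        assert stats.chi2_upper_tail(9.42, 1) == pytest.approx(0.00215, abs=5e-5)
        assert stats.chi2_upper_tail(0.0, 1) == 1.0
        assert stats.chi2_upper_tail(3.8415, 1) == pytest.approx(0.05, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(z=st.floats(-8, 8))
    def test_chi2_of_squared_z_matches_normal_tail(self, z):
        """chi2(1) tail of z^2 equals the two-sided normal tail at |z| —
        cross-checks two distribution codes."""
        assert stats.chi2_upper_tail(z * z, 1) == pytest.approx(
            2 * sps.norm.sf(abs(z)), abs=1e-10
        )


class TestTTests:
    def test_welch_reduces_to_pooled_for_equal_n_and_var(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 0.5
        res = stats.welch_t(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2)
        pooled = sps.ttest_ind(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(pooled.statistic)

    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = stats.welch_t(a, a.copy())
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_printed_t_df_pair_reproduces_p(self):
        # t(14.1) = 3.93 -> two-sided p ~ 0.0014
        assert stats.t_two_sided_p(3.93, 14.1) == pytest.approx(0.0015, abs=2e-4)

    def test_one_sample_hand_value(self):
        res = stats.one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.t_stat == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_one_sample_symmetric_values(self):
        res = stats.one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_one_sample_zero_variance_errors(self):
        with pytest.raises(ValueError):
            stats.one_sample_t([2.0, 2.0, 2.0], 0.0)


class TestSubjectZ:
    def test_reference_arithmetic(self):
        assert stats.subject_z(50.0, 50.0, 1.5).z == 0.0
        assert stats.subject_z(53.0, 50.0, 1.5).z == pytest.approx(2.0)
        assert stats.subject_z(54.4, 50.0, 1.5).z == pytest.approx(2.933, abs=1e-3)

    def test_table_lookup_and_missing_stratum(self):
        ref = pd.DataFrame(
            {"sex": ["F", "M"], "age_months": [120, 120], "mean": [52.0, 53.0],
             "sd": [1.4, 1.5]}
        )
        sz = stats.subject_z_from_table(55.0, "M", 120, ref)
        assert sz.z == pytest.approx((55 - 53) / 1.5)
        with pytest.raises(KeyError, match="sex='F'.*144"):
            stats.subject_z_from_table(55.0, "F", 144, ref)

    def test_combined_weighted_z(self):
        z, p = stats.combined_weighted_z([2.93], [1.0])
        assert z == pytest.approx(2.93)
        assert p == pytest.approx(0.0034, abs=2e-4)
        # Stouffer identity: n equal z with equal weights -> z * sqrt(n)
        z4, _ = stats.combined_weighted_z([1.2] * 4, [1.0] * 4)
        assert z4 == pytest.approx(1.2 * 2)
        z0, p0 = stats.combined_weighted_z([1.5, -1.5], [1.0, 1.0])
        assert z0 == pytest.approx(0.0)
        assert p0 == pytest.approx(1.0)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            stats.combined_weighted_z([1.0, 2.0], [0.0, 0.0])


class TestMedianScore:
    @pytest.mark.parametrize(
        "scores, expected", [((0, 1, 2), 1), ((2, 2, 0), 2), ((-1, 0, 1), 0)]
    )
    def test_middle_order_statistic(self, scores, expected):
        assert stats.median_score(scores) == expected

    def test_wrong_count(self):
        with pytest.raises(ValueError):
            stats.median_score([1, 2])
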