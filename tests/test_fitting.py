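import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nlpsens import (
    CohortSpec,
    ModelSpec,
    check_assumptions,
    estimate_propensity_weights,
    fit_model,
    generate_longitudinal_cohort,
    generate_survival_cohort,
)
from nlpsens.fitting import FitResult, _failed_fit

from oracles import or_from_2x2


def saturated_2x2_cohort(n11=20, n10=10, n01=10, n00=20):
    """exposed: n11 events / n10 non-events; unexposed: n01 / n00."""
    rows = (
        [(1, 1)] * n11 + [(1, 0)] * n10 + [(0, 1)] * n01 + [(0, 0)] * n00
    )
    df = pd.DataFrame(rows, columns=["exposure", "outcome"])
    df.insert(0, "subject_id", range(len(df)))
    return df


class TestLogisticFit:
    def test_saturated_2x2_matches_cross_product_ratio(self):
        df = saturated_2x2_cohort()
        fit = fit_model(df, ModelSpec(family="logistic", exposure="exposure"))
        expected_or = or_from_2x2(20, 10, 10, 20)  # = 4.0
        assert fit.native_estimate("exposure") == pytest.approx(expected_or, abs=1e-6)
        assert fit.coefficient("exposure") == pytest.approx(np.log(4.0), abs=1e-6)

    def test_native_estimate_is_exp_of_coefficient(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        fit = fit_model(df, logistic_spec)
        np.testing.assert_allclose(
            fit.params["native_estimate"], np.exp(fit.params["coefficient"])
        )

    def test_missing_values_rejected(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        df = df.copy()
        df.loc[0, "comorbidity"] = np.nan
        with pytest.raises(ValueError, match="comorbidity"):
            fit_model(df, logistic_spec)

    def test_exposure_override_by_array(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        override = 1 - df["observed_exposure"].to_numpy()
        fit = fit_model(df, logistic_spec, exposure_override=override)
        direct = df.copy()
        direct["observed_exposure"] = override
        fit2 = fit_model(direct, logistic_spec)
        pd.testing.assert_frame_equal(fit.params, fit2.params)

    def test_override_length_mismatch_rejected(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        with pytest.raises(ValueError, match="length"):
            fit_model(df, logistic_spec, exposure_override=np.array([0, 1]))


class TestCoxFit:
    def test_time_rescaling_invariance(self, survival_cohort, cox_spec):
        df, _ = survival_cohort
        fit = fit_model(df, cox_spec)
        scaled = df.copy()
        scaled["time"] = scaled["time"] * 10.0
        fit10 = fit_model(scaled, cox_spec)
        np.testing.assert_allclose(
            fit.params["coefficient"], fit10.params["coefficient"], atol=1e-8
        )
        np.testing.assert_allclose(fit.params["p_value"], fit10.params["p_value"], atol=1e-8)

    def test_weight_neutrality(self, survival_cohort):
        """Propensity weighting with an intercept-only model (weights
        identically 1) leaves the coefficients unchanged."""
        df, _ = survival_cohort
        unweighted = fit_model(df, ModelSpec(family="cox", exposure="observed_exposure"))
        weighted = fit_model(
            df, ModelSpec(family="cox", exposure="observed_exposure", weighting="propensity")
        )
        np.testing.assert_allclose(
            unweighted.params["coefficient"], weighted.params["coefficient"], atol=1e-8
        )


class TestLinearMixedFit:
    def test_degenerate_variance_limit_equals_group_mean_difference(self):
        spec = CohortSpec(
            n_subjects=200, outcome_family="longitudinal", true_exposure_effect=-1.43,
            baseline=30.0, exposure_prevalence=0.4, visits_per_subject=3,
            random_intercept_sd=0.0, residual_sd=1e-6,
            sensitivity=1.0, specificity=1.0, seed=21,
        )
        df = generate_longitudinal_cohort(spec)
        fit = fit_model(df, ModelSpec(family="linear_mixed", exposure="observed_exposure"))
        grp = df.groupby("observed_exposure")["measure"].mean()
        assert fit.coefficient("observed_exposure") == pytest.approx(grp[1] - grp[0], abs=1e-4)

    def test_native_estimate_is_identity(self, longitudinal_cohort, mixed_spec):
        df, _ = longitudinal_cohort
        fit = fit_model(df, mixed_spec)
        np.testing.assert_allclose(fit.params["native_estimate"], fit.params["coefficient"])


class TestWaldConvention:
    def test_p_values_are_two_sided_normal_tails(
        self, survival_cohort, binary_cohort, longitudinal_cohort, cox_spec,
        logistic_spec, mixed_spec,
    ):
        """Every family reports two-sided Wald p-values computed from
        coefficient/se."""
        for (df, _), spec in [
            (survival_cohort, cox_spec),
            (binary_cohort, logistic_spec),
            (longitudinal_cohort, mixed_spec),
        ]:
            fit = fit_model(df, spec)
            z = fit.params["coefficient"] / fit.params["se"]
            expected = 2 * stats.norm.sf(np.abs(z))
            np.testing.assert_allclose(fit.params["p_value"], expected, atol=1e-8)


class TestPropensityWeights:
    def test_no_confounders_gives_unit_weights(self, survival_cohort):
        df, _ = survival_cohort
        w = estimate_propensity_weights(df, "observed_exposure", [])
        np.testing.assert_array_equal(w, np.ones(len(df)))

    def test_independent_exposure_gives_weights_near_one(self):
        spec = CohortSpec(
            n_subjects=5000, outcome_family="survival", true_exposure_effect=0.0,
            baseline=0.1, exposure_prevalence=0.3, seed=22,
        )
        df = generate_survival_cohort(spec)
        df["z"] = np.random.default_rng(5).normal(size=len(df))
        w = estimate_propensity_weights(df, "true_exposure", ["z"])
        se = np.std(w) / np.sqrt(len(w))
        assert abs(np.mean(w) - 1.0) < 3 * se

    def test_stabilized_weights_mean_one_per_group(self, survival_cohort):
        df, spec = survival_cohort
        w = estimate_propensity_weights(df, "observed_exposure", ["age"])
        a = df["observed_exposure"].to_numpy()
        for grp in (0, 1):
            m = w[a == grp].mean()
            se = w[a == grp].std() / np.sqrt((a == grp).sum())
            assert abs(m - 1.0) < 4 * se
        assert (w > 0).all()

    def test_perfect_separation_rejected(self):
        n = 200
        z = np.linspace(-2, 2, n)
        df = pd.DataFrame({"exposure": (z > 0).astype(int), "z": z})
        with pytest.raises(ValueError, match="separation"):
            estimate_propensity_weights(df, "exposure", ["z"])


class TestAssumptionChecks:
    def test_non_converged_fit_fails_convergence_check(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        failed = _failed_fit("logistic", ["observed_exposure", "comorbidity"], len(df))
        report = check_assumptions(failed, df, logistic_spec)
        assert not report.passed
        by_name = {c.name: c for c in report.checks}
        assert not by_name["convergence"].passed

    def test_well_specified_cox_passes_ph_check(self, survival_cohort, cox_spec):
        df, _ = survival_cohort
        fit = fit_model(df, cox_spec)
        report = check_assumptions(fit, df, cox_spec)
        assert report.passed
        ph = next(c for c in report.checks if c.name == "proportional_hazards")
        assert ph.statistic > 0.01

    def test_singular_random_intercept_flagged(self):
        spec = CohortSpec(
            n_subjects=300, outcome_family="longitudinal", true_exposure_effect=-1.0,
            baseline=30.0, exposure_prevalence=0.3, visits_per_subject=3,
            random_intercept_sd=0.0, residual_sd=1.0,
            sensitivity=1.0, specificity=1.0, seed=102,
        )
        df = generate_longitudinal_cohort(spec)
        ms = ModelSpec(family="linear_mixed", exposure="observed_exposure")
        fit = fit_model(df, ms)
        report = check_assumptions(fit, df, ms)
        singular = next(c for c in report.checks if c.name == "random_effects_nonsingular")
        assert not singular.passed
        assert not report.passed

    def test_genuine_random_intercept_not_flagged(self, longitudinal_cohort, mixed_spec):
        df, _ = longitudinal_cohort
        fit = fit_model(df, mixed_spec)
        report = check_assumptions(fit, df, mixed_spec)
        assert report.passed

    def test_report_round_trips_through_dict(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        fit = fit_model(df, logistic_spec)
        report = check_assumptions(fit, df, logistic_spec)
        from nlpsens.fitting import AssumptionReport

        back = AssumptionReport.from_dict(report.to_dict())
        assert back.passed == report.passed
        assert [c.name for c in back.checks] == [c.name for c in report.checks]


class TestModelSpecValidation:
    def test_missing_columns_named(self, binary_cohort):
        df, _ = binary_cohort
        spec = ModelSpec(family="logistic", exposure="nope", confounders=["also_nope"])
        with pytest.raises(ValueError, match="nope"):
            spec.validate(df)

    def test_weighting_restricted_to_cox(self, binary_cohort):
        df, _ = binary_cohort
        spec = ModelSpec(family="logistic", exposure="observed_exposure", weighting="propensity")
        with pytest.raises(ValueError, match="cox"):
            spec.validate(df)

    def test_fit_result_round_trips_through_dict(self, binary_cohort, logistic_spec):
        df, _ = binary_cohort
        fit = fit_model(df, logistic_spec)
        back = FitResult.from_dict(fit.to_dict())
        pd.testing.assert_frame_equal(back.params, fit.params)
        assert back.converged == fit.converged and back.n_obs == fit.n_obs
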