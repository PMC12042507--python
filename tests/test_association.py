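import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from nc886proxy import (
    bh_fdr,
    fit_linear,
    fit_logistic,
    inverse_normal_transform,
    run_cohort_associations,
)
from nc886proxy.association import results_to_frame
from nc886proxy.errors import (
    CollinearityError,
    InputError,
    InsufficientDataError,
)


class TestInverseNormalTransform:
    def test_three_distinct_values(self):
        # Blom scores for m=3: Phi^-1((r - 3/8) / 3.25)
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        expected = norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        assert out == pytest.approx(expected)
        assert out[0] == pytest.approx(-0.8694, abs=1e-4)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_input_sums_to_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 3.0, 2.0, 4.0])
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    def test_all_tied_values_map_to_zero(self):
        out = inverse_normal_transform([7.0] * 6)
        assert out == pytest.approx(np.zeros(6))

    def test_missing_values_stay_missing(self):
        s = pd.Series([1.0, np.nan, 3.0, 2.0], index=list("abcd"))
        out = inverse_normal_transform(s)
        assert np.isnan(out["b"])
        assert not out.drop("b").isna().any()

    def test_rank_preserving_and_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=2000)
        out = inverse_normal_transform(x)
        assert np.array_equal(np.argsort(x), np.argsort(out))
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=0.02)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(InputError):
            inverse_normal_transform([1.0, np.nan])


def _frame(y, elevated, **covs):
    return pd.DataFrame({"y": y, "elevated": elevated, **covs})


class TestFitLinear:
    def test_perfect_fit_is_flagged(self):
        data = _frame([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1])
        result = fit_linear(data, "y", covariates=())
        assert result.estimate == pytest.approx(1.0)
        assert "zero residual variance" in result.note

    def test_matches_normal_equations_oracle(self):
        # small worked dataset, coefficients checked against a direct
        # normal-equations solve
        data = pd.DataFrame(
            {
                "y": [1.2, 0.8, 1.9, 2.3, 0.5, 1.1, 2.8, 2.0],
                "elevated": [0, 0, 0, 0, 1, 1, 1, 1],
                "age": [34.0, 41.0, 38.0, 44.0, 31.0, 39.0, 45.0, 36.0],
                "sex": [0, 1, 0, 1, 0, 1, 0, 1],
            }
        )
        result = fit_linear(data, "y", covariates=("age", "sex"))
        X = np.column_stack(
            [np.ones(8), data["elevated"], data["age"], data["sex"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"].to_numpy())
        assert result.estimate == pytest.approx(beta[1], abs=1e-10)
        resid = data["y"].to_numpy() - X @ beta
        sigma2 = resid @ resid / (8 - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert result.se == pytest.approx(se, abs=1e-10)

    def test_collinear_design_names_columns(self):
        data = _frame([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 1, 1, 1], age=[1.0] * 5)
        with pytest.raises(CollinearityError) as err:
            fit_linear(data, "y", covariates=("age",))
        assert "age" in err.value.columns or "const" in err.value.columns

    def test_complete_case_drops_are_counted(self):
        data = _frame([1.0, np.nan, 3.0, 4.0, 2.0, 5.0], [0, 0, 1, 1, 0, 1])
        result = fit_linear(data, "y", covariates=())
        assert result.n == 5
        assert result.dropped_rows == 1


class TestFitLogistic:
    def test_two_by_two_matches_cross_product_oracle(self):
        # cases/controls: 30/70 elevated, 20/80 control -> OR = (30*80)/(70*20)
        y = [1] * 30 + [0] * 70 + [1] * 20 + [0] * 80
        elevated = [1] * 100 + [0] * 100
        result = fit_logistic(_frame(y, elevated), "y", covariates=())
        oracle_or = (30 * 80) / (70 * 20)
        assert result.odds_ratio == pytest.approx(oracle_or, abs=1e-10)
        wald_se = np.sqrt(1 / 30 + 1 / 70 + 1 / 20 + 1 / 80)
        assert result.se == pytest.approx(wald_se, abs=1e-10)
        assert result.ci_low == pytest.approx(
            np.exp(np.log(oracle_or) - 1.96 * wald_se), rel=1e-3
        )

    def test_single_outcome_class_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            fit_logistic(_frame([1] * 50, [0] * 25 + [1] * 25), "y", covariates=())

    def test_case_threshold(self):
        y = [1] * 10 + [0] * 90
        elevated = ([1, 0] * 50)[:100]
        with pytest.raises(InsufficientDataError, match="cases"):
            fit_logistic(_frame(y, elevated), "y", covariates=(), min_cases=10)

    def test_null_consistency_at_large_n(self):
        rng = np.random.default_rng(1)
        n = 20000
        data = _frame(
            (rng.random(n) < 0.2).astype(int),
            (rng.random(n) < 0.3).astype(int),
            age=rng.uniform(30, 45, n),
            sex=rng.integers(0, 2, n).astype(float),
        )
        result = fit_logistic(data, "y", covariates=("age", "sex"))
        assert abs(result.estimate) < 0.05


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_step_up_oracle_on_random_lists(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            adjusted = np.empty(m)
            running_min = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                running_min = min(running_min, p[idx] * m / rank)
                adjusted[idx] = running_min
            return adjusted

        rng = np.random.default_rng(9)
        for size in (2, 3, 5, 8, 10):
            p = rng.random(size)
            assert bh_fdr(p) == pytest.approx(oracle(p), abs=1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])


def _cohort_tables(n, rng, effect=0.0, prevalence=0.2, log_or=0.0):
    elevated = rng.random(n) < 0.3
    assignments = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "usage": np.where(elevated, "elevated", "control"),
        }
    )
    logit = np.log(prevalence / (1 - prevalence)) + log_or * elevated
    phenotypes = pd.DataFrame(
        {
            "sample_id": assignments["sample_id"],
            "age": rng.uniform(30, 45, n),
            "sex": rng.integers(0, 2, n),
            "fasting": rng.integers(0, 2, n),
            "diastolic_bp": rng.standard_normal(n) + effect * elevated,
            "type2_diabetes": (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
        }
    )
    return assignments, phenotypes


class TestRunCohortAssociations:
    def test_configured_shift_is_recovered_with_positive_sign(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(10):
            assignments, phenotypes = _cohort_tables(1500, rng, effect=0.3)
            results, _ = run_cohort_associations(
                assignments,
                phenotypes,
                continuous_outcomes=("diastolic_bp",),
                binary_outcomes=(),
                strata=("all",),
            )
            hits += results[0].estimate > 0
        assert hits == 10

    def test_low_case_outcome_is_skipped_with_reason(self):
        rng = np.random.default_rng(2)
        assignments, phenotypes = _cohort_tables(400, rng)
        phenotypes["type2_diabetes"] = 0
        phenotypes.loc[phenotypes.index[:9], "type2_diabetes"] = 1
        results, skipped = run_cohort_associations(
            assignments,
            phenotypes,
            continuous_outcomes=(),
            binary_outcomes=("type2_diabetes",),
            strata=("all",),
        )
        assert not results
        assert any(s.outcome == "type2_diabetes" and "cases" in s.reason for s in skipped)

    def test_empty_elevated_group_skips_every_outcome(self):
        rng = np.random.default_rng(3)
        assignments, phenotypes = _cohort_tables(200, rng)
        assignments["usage"] = "control"
        results, skipped = run_cohort_associations(
            assignments,
            phenotypes,
            continuous_outcomes=("diastolic_bp",),
            binary_outcomes=("type2_diabetes",),
            strata=("all",),
        )
        assert not results
        assert len(skipped) == 2

    def test_fdr_families_are_per_stratum_and_model(self):
        rng = np.random.default_rng(4)
        assignments, phenotypes = _cohort_tables(2000, rng, prevalence=0.3)
        phenotypes["glucose"] = rng.standard_normal(2000)
        results, _ = run_cohort_associations(
            assignments,
            phenotypes,
            continuous_outcomes=("diastolic_bp", "glucose"),
            binary_outcomes=("type2_diabetes",),
            strata=("all", "women"),
        )
        frame = results_to_frame(results)
        assert set(frame["stratum"]) == {"all", "women"}
        for (_, model), family in frame.groupby(["stratum", "model"]):
            expected = bh_fdr(family["p"].to_numpy())
            assert family["q"].to_numpy() == pytest.approx(expected)
        # q >= p within every family
        assert (frame["q"] >= frame["p"] - 1e-12).all()

    def test_sex_stratified_fits_drop_the_sex_covariate(self):
        rng = np.random.default_rng(5)
        assignments, phenotypes = _cohort_tables(1000, rng)
        results, skipped = run_cohort_associations(
            assignments,
            phenotypes,
            continuous_outcomes=("diastolic_bp",),
            binary_outcomes=(),
            strata=("women",),
        )
        # a constant sex column inside the stratum would be collinear if kept
        assert results and results[0].stratum == "women"
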