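import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_auc, make_cohort

from tsscore.cohort import Cohort
from tsscore.errors import (
    DomainError,
    GroupingError,
    SeparationError,
    SingularDesignError,
    UndefinedCorrelationError,
)
from tsscore.scoring import SUBSCORE_FIELDS
from tsscore.synthetic import GeneratorConfig, derive_model_intercept, generate_cohort
from tsscore.validation import (
    calibration_by_score,
    confusion_metrics,
    fit_logistic,
    fit_statistics,
    group_compare,
    hosmer_lemeshow,
    odds_ratio_transform,
    proportion_z_test,
    roc_analysis,
    spearman_correlation,
    vif,
)


class TestLogisticFit:
    def test_recovers_generating_slope(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        assert fit.converged
        assert fit.ci_low[1] <= -0.597 <= fit.ci_high[1]

    def test_wald_type_one_error_with_null_slope(self):
        # outcome independent of the score: |beta1| < 2 SE in most replicates
        beta0 = float(np.log(0.082 / 0.918))
        hits = 0
        for i in range(100):
            c = generate_cohort(
                GeneratorConfig(mode="model_based", beta1=0.0, beta0=beta0, seed=5000 + i)
            )
            fit = fit_logistic(c, ["tss_total"])
            hits += abs(fit.coefficients[1]) < 2 * fit.standard_errors[1]
        assert hits >= 90

    def test_zero_variance_covariate_raises(self):
        c = generate_cohort(GeneratorConfig(seed=0))
        c.frame["flat"] = 0.0
        with pytest.raises(SingularDesignError):
            fit_logistic(c, ["flat"])

    def test_perfect_separation_raises(self):
        totals = [0, 1, 2, 3, 5, 6, 7, 8] * 10
        outcomes = [1 if t <= 3 else 0 for t in totals]
        with pytest.raises(SeparationError):
            fit_logistic(make_cohort(totals, outcomes), ["tss_total"])

    def test_single_class_outcome_raises(self):
        with pytest.raises(DomainError):
            fit_logistic(make_cohort([1, 2, 3, 4], [0, 0, 0, 0]), ["tss_total"])

    def test_ci_brackets_estimate_and_likelihood_ordering(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        assert np.all(fit.ci_low <= fit.coefficients)
        assert np.all(fit.coefficients <= fit.ci_high)
        assert fit.log_likelihood >= fit.null_log_likelihood
        assert np.all(fit.odds_ratios > 0)


class TestOddsRatioTransform:
    def test_published_per_point_odds_ratio_algebra(self):
        # exponentiating the reported coefficient and CI bounds
        assert np.exp(-0.597) == pytest.approx(0.551, abs=1e-3)
        assert np.exp(-0.764) == pytest.approx(0.466, abs=1e-3)
        assert np.exp(-0.430) == pytest.approx(0.651, abs=1e-3)

    def test_transform_is_exp_and_order_preserving(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        table = odds_ratio_transform(fit)
        assert np.allclose(table["odds_ratio"], np.exp(table["beta"]))
        assert np.allclose(table["or_ci_low"], np.exp(table["ci_low"]))
        assert (table["or_ci_low"] <= table["odds_ratio"]).all()
        assert (table["odds_ratio"] <= table["or_ci_high"]).all()
        assert list(table["term"]) == ["const", "tss_total"]

    def test_zero_coefficient_maps_to_unit_odds(self):
        assert np.exp(0.0) == 1.0


class TestVif:
    def test_orthogonal_covariates_have_unit_vif(self):
        totals = [0, 1, 2, 3] * 25
        outcomes = ([1, 0, 0, 0] * 25)
        c = make_cohort(totals, outcomes)
        c.frame["a"] = [0.0, 1.0] * 50
        c.frame["b"] = [0.0, 0.0, 1.0, 1.0] * 25
        values = vif(c, ["a", "b"])
        assert values["a"] == pytest.approx(1.0, abs=1e-9)
        assert values["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_covariate_is_singular(self):
        c = generate_cohort(GeneratorConfig(seed=2))
        c.frame["dup"] = c.frame["tad_score"]
        values = vif(c, ["tad_score", "dup"])
        assert np.isinf(values["tad_score"]) and np.isinf(values["dup"])

    def test_default_generator_subscores_below_five(self, default_cohorts):
        values = vif(default_cohorts[0], list(SUBSCORE_FIELDS))
        assert all(1.0 <= v < 5.0 for v in values.values())

    def test_zero_variance_covariate_raises(self):
        c = generate_cohort(GeneratorConfig(seed=2))
        c.frame["flat"] = 1.0
        with pytest.raises(DomainError):
            vif(c, ["tad_score", "flat"])


class TestRocAnalysis:
    @pytest.mark.parametrize(
        "totals, outcomes, expected",
        [
            ([1, 2, 7, 8], [1, 1, 0, 0], 1.0),   # complete separation
            ([1, 7, 2, 8], [1, 1, 0, 0], 0.75),  # 3 of 4 pairs concordant
            ([4, 4, 4, 4], [1, 1, 0, 0], 0.5),   # no discrimination
        ],
    )
    def test_worked_auc_values(self, totals, outcomes, expected):
        assert roc_analysis(make_cohort(totals, outcomes)).auc == pytest.approx(expected)

    def test_trapezoid_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(314)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            totals = rng.integers(0, 9, size=n)
            outcomes = rng.integers(0, 2, size=n)
            if outcomes.sum() in (0, n):
                outcomes[0] = 1 - outcomes[0]
            c = make_cohort(totals, outcomes)
            oracle = brute_force_auc(outcomes, -totals.astype(float))
            assert roc_analysis(c).auc == pytest.approx(oracle, abs=1e-12)

    def test_perfect_separation_has_unit_youden_j(self):
        r = roc_analysis(make_cohort([1, 2, 7, 8], [1, 1, 0, 0]))
        assert r.auc == pytest.approx(1.0)
        assert r.youden_j == pytest.approx(1.0)

    def test_fitted_probabilities_and_raw_score_agree(self, default_cohorts):
        c = default_cohorts[1]
        fit = fit_logistic(c, ["tss_total"])
        with_fit = roc_analysis(c, fit=fit)
        without = roc_analysis(c)
        assert with_fit.auc == pytest.approx(without.auc, abs=1e-12)
        assert with_fit.youden_tss_cutoff == without.youden_tss_cutoff
        assert with_fit.youden_threshold_probability is not None

    def test_single_class_raises(self):
        with pytest.raises(DomainError):
            roc_analysis(make_cohort([1, 2, 3], [1, 1, 1]))


class TestConfusionMetrics:
    def test_everything_positive_at_cutoff_eight(self, default_cohorts):
        cm = confusion_metrics(default_cohorts[2], 8)
        assert cm.sensitivity == 1.0
        assert cm.specificity == 0.0

    def test_nothing_positive_below_minimum(self, default_cohorts):
        cm = confusion_metrics(default_cohorts[2], -1)
        assert cm.sensitivity == 0.0
        assert cm.specificity == 1.0

    def test_accuracy_identity_at_every_cutoff(self, default_cohorts):
        c = default_cohorts[3]
        n_pos = int(c.outcome.sum())
        n_neg = c.n - n_pos
        for cutoff in range(-1, 9):
            cm = confusion_metrics(c, cutoff)
            assert cm.accuracy == pytest.approx(
                (cm.sensitivity * n_pos + cm.specificity * n_neg) / c.n
            )


class TestHosmerLemeshow:
    def test_well_calibrated_model_usually_passes(self):
        good = 0
        for i in range(100):
            c = generate_cohort(GeneratorConfig(n=5000, mode="model_based", seed=3000 + i))
            fit = fit_logistic(c, ["tss_total"])
            good += hosmer_lemeshow(c, fit).hl_p > 0.05
        assert good >= 90

    def test_grossly_miscalibrated_model_usually_fails(self):
        bad = 0
        for i in range(100):
            c = generate_cohort(GeneratorConfig(n=5000, mode="model_based", seed=3000 + i))
            fit = fit_logistic(c, ["tss_total"])
            squared = fit.predict(c.frame) ** 2
            bad += hosmer_lemeshow(c, probabilities=squared).hl_p < 0.05
        assert bad >= 90

    def test_statistic_zero_when_groups_perfectly_calibrated(self):
        # observed rate equals the constant prediction within each group
        totals = [2] * 10 + [5] * 10 + [8] * 10
        outcomes = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0] + [1, 1, 0, 0, 0, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        c = make_cohort(totals, outcomes)
        probs = np.repeat([0.4, 0.2, 0.1], 10)
        d = hosmer_lemeshow(c, probabilities=probs, n_groups=3)
        assert d.hosmer_lemeshow_statistic == pytest.approx(0.0, abs=1e-12)
        assert d.hl_p == pytest.approx(1.0)

    def test_single_group_request_raises(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        with pytest.raises(GroupingError):
            hosmer_lemeshow(model_cohort_5000, fit, n_groups=1)

    def test_too_few_distinct_predictions_raises(self):
        totals = [2] * 20 + [5] * 20
        outcomes = [1] * 5 + [0] * 15 + [1] * 2 + [0] * 18
        c = make_cohort(totals, outcomes)
        with pytest.raises(GroupingError):
            hosmer_lemeshow(c, probabilities=np.repeat([0.25, 0.1], 20))


class TestFitStatistics:
    def test_null_covariate_gives_near_zero_mcfadden(self):
        beta0 = float(np.log(0.082 / 0.918))
        c = generate_cohort(GeneratorConfig(n=5000, mode="model_based", beta1=0.0,
                                            beta0=beta0, seed=9))
        fit = fit_logistic(c, ["tss_total"])
        assert fit_statistics(fit).mcfadden_r2 == pytest.approx(0.0, abs=0.01)

    def test_lr_statistic_behaves_as_null_chi_square_without_signal(self):
        # under a zero-slope generator the LR statistic is chi2(1);
        # its median across seeds should sit near 0.455, far below signal
        beta0 = float(np.log(0.082 / 0.918))
        lrs = []
        for seed in range(20):
            c = generate_cohort(GeneratorConfig(n=5000, mode="model_based",
                                                beta1=0.0, beta0=beta0, seed=seed))
            d = fit_statistics(fit_logistic(c, ["tss_total"]))
            assert d.lr_statistic >= 0.0
            assert 0.0 <= d.lr_p <= 1.0
            lrs.append(d.lr_statistic)
        assert float(np.median(lrs)) < 2.0

    def test_mcfadden_envelope_matches_published_fit(self):
        values = []
        for i in range(100):
            c = generate_cohort(GeneratorConfig(mode="model_based", seed=4000 + i))
            values.append(fit_statistics(fit_logistic(c, ["tss_total"])).mcfadden_r2)
        assert 0.10 <= float(np.median(values)) <= 0.25

    def test_mcfadden_invariant_to_outcome_relabeling(self, default_cohorts):
        c = default_cohorts[4]
        fit = fit_logistic(c, ["tss_total"])
        flipped = Cohort(c.frame.assign(outcome=1 - c.frame["outcome"]), validate=False)
        fit_flipped = fit_logistic(flipped, ["tss_total"])
        assert fit_statistics(fit).mcfadden_r2 == pytest.approx(
            fit_statistics(fit_flipped).mcfadden_r2, abs=1e-8
        )
        assert fit_flipped.coefficients[1] == pytest.approx(-fit.coefficients[1], abs=1e-6)


class TestGroupCompare:
    def test_null_distribution_of_p_values(self):
        rng = np.random.default_rng(99)
        calm = 0
        for _ in range(100):
            totals = rng.integers(0, 9, size=200)
            outcomes = rng.random(200) < 0.25
            if outcomes.sum() in (0, 200):
                outcomes[0] = ~outcomes[0]
            c = make_cohort(totals, outcomes.astype(int))
            calm += group_compare(c, "tss_total", "continuous").p > 0.05
        assert calm >= 90

    def test_power_at_published_group_separation(self, default_cohorts):
        strong = sum(
            group_compare(c, "tss_total", "continuous").p < 0.001
            for c in default_cohorts
        )
        assert strong >= 95

    def test_u_statistic_complete_separation(self):
        c = make_cohort([1, 2, 3, 4], [1, 1, 0, 0])
        res = group_compare(c, "tss_total", "continuous")
        assert res.statistic == 0.0  # every complication scores below every control

    def test_continuous_summaries_match_describe(self, default_cohorts):
        res = group_compare(default_cohorts[5], "tss_total", "continuous")
        comp = res.summaries["complication"]
        assert set(comp) == {"n", "mean", "sd", "min", "max", "median"}
        assert comp["min"] <= comp["median"] <= comp["max"]

    def test_categorical_chi_square(self, default_cohorts):
        res = group_compare(default_cohorts[6], "quadrant_ap", "categorical")
        assert res.statistic >= 0
        assert 0 <= res.p <= 1
        assert res.contingency is not None

    def test_empty_group_raises(self):
        with pytest.raises(DomainError):
            group_compare(make_cohort([1, 2], [0, 0]), "tss_total", "continuous")


class TestProportionZTest:
    def test_equal_proportions(self):
        z, p = proportion_z_test(5, 10, 10, 20)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_superior_posterior_contrast(self):
        # 25% vs 4.6% superior-posterior placements
        _, p = proportion_z_test(12, 48, 25, 538)
        assert p < 0.001

    def test_published_centre_centre_contrast(self):
        # 18.8% vs 35.5% centre-centre placements
        _, p = proportion_z_test(9, 48, 191, 538)
        assert p < 0.05

    def test_out_of_range_counts_raise(self):
        with pytest.raises(DomainError):
            proportion_z_test(11, 10, 5, 10)


class TestSpearman:
    def test_perfect_monotone_relationships(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman_correlation(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_acs_outcome_envelope_matches_published_correlation(self, default_cohorts):
        rhos = [
            spearman_correlation(c.frame["acs_score"].to_numpy(float), c.outcome)[0]
            for c in default_cohorts
        ]
        median = float(np.median(rhos))
        assert -0.45 <= median <= -0.15  # published value -0.296


class TestCalibrationByScore:
    def test_model_generated_cohort_is_calibrated(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        table = calibration_by_score(model_cohort_5000, fit)
        busy = table[table["n"] >= 20]
        gap = (busy["observed_rate"] - busy["predicted_rate"]).abs().mean()
        assert gap < 0.05

    def test_predicted_column_decreasing_for_protective_fit(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        table = calibration_by_score(model_cohort_5000, fit)
        predicted = table["predicted_rate"].to_numpy()
        assert np.all(np.diff(predicted) < 0)

    def test_absent_level_is_flagged_not_fabricated(self, model_cohort_5000):
        fit = fit_logistic(model_cohort_5000, ["tss_total"])
        trimmed = Cohort(
            model_cohort_5000.frame[model_cohort_5000.frame["tss_total"] != 0],
            validate=False,
        )
        table = calibration_by_score(trimmed, fit)
        row = table[table["tss_total"] == 0].iloc[0]
        assert not row["present"]
        assert np.isnan(row["observed_rate"])
        # model value still reported for the absent level of a score-only fit
        assert 0.0 < row["predicted_rate"] < 1.0
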